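"""Validation experiments on synthetic data with known ground truth.

These mirror how the screening method is validated scientifically:
calibration of the ternary calls on pure-noise data, recovery of a planted
signature induction, concordance of profiles across independent
experiments applying the same perturbation, and end-to-end recovery of
planted mimetic compounds in a full bait-vs-probe screen.

Problem sizes default to a reduced gene count (a few hundred genes, one
probe per gene, signatures of 8-10 genes) so a full experiment runs in
minutes on one CPU; the statistical properties under test do not depend on
the gene count.  All replicate seeds derive from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .gsea import score_study
from .io import SignatureSet
from .pipeline import match_groups
from .records import SimilaritySummary
from .screen import screen_compounds
from .simulate import SimulationConfig, simulate_bait_and_probe, simulate_study

#: Bait profile used by the screen experiments: six induced, four repressed
#: signatures out of twenty — a profile with clear structure on half the
#: signature panel, like a strong dietary perturbation.
DEFAULT_BAIT_DIRECTIONS = {
    **{f"SIG_{i:02d}": 1 for i in range(1, 7)},
    **{f"SIG_{i:02d}": -1 for i in range(7, 11)},
}


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass(frozen=True)
class NullCalibrationResult:
    n_tests: int
    n_nonzero: int

    @property
    def rate(self) -> float:
        return self.n_nonzero / self.n_tests


def null_call_calibration(
    n_compounds: int = 13,
    n_treated: int = 2,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullCalibrationResult:
    """Fraction of nonzero ternary calls on exchangeable-noise data.

    No effects are planted, so every (sample, signature) test is null; at
    level ``alpha`` the nonzero-call rate should be at most about
    ``2 * alpha`` (one test per tail, minus the overlap).
    """
    config = SimulationConfig(
        n_genes=200, probes_per_gene=1, n_signatures=20, genes_per_signature=8,
        noise_sd=0.25, effect_size=0.0, n_control=3, n_treated=n_treated,
        n_compounds=n_compounds, conditions_per_compound=1,
        mimetic_compounds=(), mimetic_directions={}, seed=seed,
    )
    result = simulate_study(config)
    # truth must confirm the null construction before we interpret calls
    assert all(d == 0 for sigmap in result.truth.directions.values()
               for d in sigmap.values())
    scored = score_study(result.study, result.signatures, n_perm=n_perm,
                         alpha=alpha, seed=seed)
    n_tests = n_nonzero = 0
    for profile in scored.profiles:
        for r in profile.results:
            if r.flag in ("ok", "weight_fallback"):
                n_tests += 1
                n_nonzero += r.call != 0
    return NullCalibrationResult(n_tests=n_tests, n_nonzero=n_nonzero)


@dataclass(frozen=True)
class RecoveryResult:
    n_replicates: int
    n_recovered: int

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_replicates


def planted_recovery(
    n_replicates: int = 100,
    effect_size: float = 1.0,
    noise_sd: float = 0.25,
    n_control: int = 3,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> RecoveryResult:
    """How often a planted signature induction is called +1.

    Each replicate simulates a fresh study with the effect planted on one
    signature in one treated sample and scores that signature.
    """
    n_recovered = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        config = SimulationConfig(
            n_genes=200, probes_per_gene=1, n_signatures=20, genes_per_signature=8,
            noise_sd=noise_sd, effect_size=effect_size, n_control=n_control,
            n_treated=1, n_compounds=1, conditions_per_compound=1,
            mimetic_compounds=("CPD_01",), mimetic_directions={"SIG_01": 1},
            seed=rep_seed,
        )
        result = simulate_study(config)
        assert result.truth.direction("CPD_01_c1", "SIG_01") == 1
        target: SignatureSet = result.signatures.subset(["SIG_01"])
        scored = score_study(result.study, target, n_perm=n_perm, alpha=alpha,
                             seed=rep_seed)
        (profile,) = scored.profiles
        n_recovered += profile.results[0].call == 1
    return RecoveryResult(n_replicates=n_replicates, n_recovered=n_recovered)


@dataclass(frozen=True)
class ConcordanceResult:
    """Median pairwise profile correlation between two independent
    experiments applying the same perturbation, per seed."""

    summaries: tuple[SimilaritySummary, ...]

    @property
    def median_pccs(self) -> list[float]:
        return [s.q50 for s in self.summaries]

    @property
    def n_positive_medians(self) -> int:
        return sum(q > 0 for q in self.median_pccs)

    @property
    def overall_median(self) -> float:
        return median(self.median_pccs)


def cross_experiment_concordance(
    n_seeds: int = 20,
    n_perm: int = 2_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ConcordanceResult:
    """Profile concordance across two independent synthetic experiments.

    Both experiments plant the same six-up/four-down direction map (on a
    ten-signature panel) with independent baselines and noise; the summary
    is the quantile spread of all cross-experiment profile correlations.
    """
    directions = {f"SIG_{i:02d}": (1 if i <= 3 else -1) for i in range(1, 7)}
    summaries = []
    for rep_seed in _replicate_seeds(seed, n_seeds):
        config = SimulationConfig(
            n_genes=150, probes_per_gene=1, n_signatures=10, genes_per_signature=10,
            noise_sd=0.25, effect_size=1.0, n_control=3, n_treated=3,
            n_compounds=1, conditions_per_compound=1,
            mimetic_compounds=("CPD_01",), seed=rep_seed,
        )
        pair = simulate_bait_and_probe(config, directions)
        bait = score_study(pair.bait_study, pair.signatures, n_perm=n_perm,
                           alpha=alpha, seed=rep_seed, null_sharing="sample")
        probe = score_study(pair.probe_study, pair.signatures, n_perm=n_perm,
                            alpha=alpha, seed=rep_seed, null_sharing="sample")
        (summary,) = match_groups(bait.profiles, probe.profiles,
                                  pair.probe_study.groups, pair.manifest,
                                  pair.bait_group)
        summaries.append(summary)
    return ConcordanceResult(summaries=tuple(summaries))


@dataclass(frozen=True)
class ScreenTrial:
    seed: int
    hits: tuple[str, ...]
    mimetics: tuple[str, ...]

    @property
    def recovered_all(self) -> bool:
        return set(self.mimetics) <= set(self.hits)

    @property
    def n_false_positives(self) -> int:
        return len(set(self.hits) - set(self.mimetics))


@dataclass(frozen=True)
class ScreenRecoveryResult:
    trials: tuple[ScreenTrial, ...]
    max_false_positives_allowed: int = 1

    @property
    def n_success(self) -> int:
        return sum(
            t.recovered_all and t.n_false_positives <= self.max_false_positives_allowed
            for t in self.trials
        )

    @property
    def success_rate(self) -> float:
        return self.n_success / len(self.trials)

    @property
    def mean_false_positives(self) -> float:
        return float(np.mean([t.n_false_positives for t in self.trials]))


def screen_recovery(
    n_seeds: int = 25,
    n_compounds: int = 20,
    conditions_per_compound: int = 4,
    n_mimetics: int = 3,
    effect_size: float = 1.0,
    noise_sd: float = 0.25,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    screen_alpha: float = 0.05,
    seed: int = 0,
) -> ScreenRecoveryResult:
    """End-to-end screen: plant mimetic compounds, run the full pipeline,
    check they are recovered as compound hits with few false positives.

    Scoring uses the per-sample shared permutation null so that a full
    multi-seed experiment stays desk-scale.
    """
    mimetics = tuple(f"CPD_{i:02d}" for i in range(1, n_mimetics + 1))
    trials = []
    for rep_seed in _replicate_seeds(seed, n_seeds):
        config = SimulationConfig(
            n_genes=260, probes_per_gene=1, n_signatures=20, genes_per_signature=10,
            noise_sd=noise_sd, effect_size=effect_size, n_control=3, n_treated=2,
            n_compounds=n_compounds, conditions_per_compound=conditions_per_compound,
            mimetic_compounds=mimetics, seed=rep_seed,
        )
        pair = simulate_bait_and_probe(config, DEFAULT_BAIT_DIRECTIONS,
                                       n_bait_samples=4)
        truth_mimetics = tuple(sorted(c for c, m in pair.truth.mimetics.items() if m))
        bait = score_study(pair.bait_study, pair.signatures, n_perm=n_perm,
                           alpha=alpha, seed=rep_seed, null_sharing="sample")
        probe = score_study(pair.probe_study, pair.signatures, n_perm=n_perm,
                            alpha=alpha, seed=rep_seed, null_sharing="sample")
        summaries = match_groups(bait.profiles, probe.profiles,
                                 pair.probe_study.groups, pair.manifest,
                                 pair.bait_group)
        result = screen_compounds(summaries, pair.manifest,
                                  screen_alpha=screen_alpha,
                                  bait_id=pair.bait_group)
        trials.append(ScreenTrial(
            seed=rep_seed,
            hits=tuple(sorted(r.compound for r in result.hits())),
            mimetics=truth_mimetics,
        ))
    return ScreenRecoveryResult(trials=tuple(trials))
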