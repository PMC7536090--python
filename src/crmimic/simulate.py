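"""Synthetic probe-level expression studies with known ground truth.

The generator emulates RMA-style microarray data: log2-scale signals that
are approximately Gaussian per probe.  Each gene draws a baseline once
from Normal(baseline_mean, baseline_sd); every probe of that gene inherits
the baseline; each replicate adds Normal(0, noise_sd) noise; treated
groups additionally add ``effect_size * direction`` to every probe of
every gene in a planted signature.  Probes map many-to-one onto genes.

Compound layouts mirror a toxicology screen: each compound is tested under
several (dose, duration) conditions, each with its own treated group; all
treated groups share one vehicle control group, as in screens where many
compounds share the same vehicle arm.

Everything is deterministic given the master seed, and the planted truth
is emitted alongside the data so recovery tests can read it from the
record rather than from the configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ConditionManifest, ExpressionStudy, SignatureSet
from .records import Condition, GroundTruth

CONTROL_GROUP = "CTRL"
BAIT_GROUP = "CR"


def compound_name(i: int) -> str:
    return f"CPD_{i:02d}"


def signature_name(i: int) -> str:
    return f"SIG_{i:02d}"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a liver-microarray-like study: 2000 genes with 1-3
    probes each, 20 disjoint signatures of 50 genes, RMA-like baselines
    (log2 mean 7, sd 1.5 across genes), replicate noise sd 0.25 (log2),
    planted effects of 1.0 log2 units, and groups of 3 control / 3 treated
    animals.
    """

    n_genes: int = 2000
    probes_per_gene: int | tuple[int, int] = (1, 3)
    n_signatures: int = 20
    genes_per_signature: int = 50
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    effect_size: float = 1.0
    n_control: int = 3
    n_treated: int = 3
    n_compounds: int = 1
    conditions_per_compound: int = 1
    mimetic_compounds: tuple[str, ...] = ()
    mimetic_directions: dict[str, int] = field(default_factory=dict)
    decoy_compounds: tuple[str, ...] = ()
    decoy_directions: dict[str, int] = field(default_factory=dict)
    allow_signature_overlap: bool = False
    seed: int = 0

    def compound_names(self) -> tuple[str, ...]:
        return tuple(compound_name(i + 1) for i in range(self.n_compounds))

    def signature_names(self) -> tuple[str, ...]:
        return tuple(signature_name(i + 1) for i in range(self.n_signatures))

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_signatures": self.n_signatures,
            "genes_per_signature": self.genes_per_signature,
            "n_control": self.n_control,
            "n_treated": self.n_treated,
            "n_compounds": self.n_compounds,
            "conditions_per_compound": self.conditions_per_compound,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1, got {v}")
        if self.n_control < 2:
            raise ValidationError("n_control must be >= 2 (control mean needs >= 2 samples)")
        for name, v in (("baseline_sd", self.baseline_sd), ("noise_sd", self.noise_sd)):
            if v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if isinstance(self.probes_per_gene, tuple):
            lo, hi = self.probes_per_gene
            if lo < 1 or hi < lo:
                raise ValidationError(f"invalid probes_per_gene range {self.probes_per_gene}")
        elif self.probes_per_gene < 1:
            raise ValidationError("probes_per_gene must be >= 1")
        if (not self.allow_signature_overlap
                and self.n_signatures * self.genes_per_signature > self.n_genes):
            raise ValidationError(
                "disjoint signatures need n_signatures * genes_per_signature <= n_genes"
            )
        names = set(self.compound_names())
        for label, group in (("mimetic", self.mimetic_compounds),
                             ("decoy", self.decoy_compounds)):
            extra = set(group) - names
            if extra:
                raise ValidationError(f"{label} compounds not in compound set: {sorted(extra)}")
        signames = set(self.signature_names())
        for label, dirs in (("mimetic", self.mimetic_directions),
                            ("decoy", self.decoy_directions)):
            _validate_directions(dirs, signames, label)


def _validate_directions(directions: Mapping[str, int], signature_names: set[str],
                         label: str) -> None:
    for sig, d in directions.items():
        if sig not in signature_names:
            raise ValidationError(f"{label} direction for unknown signature '{sig}'")
        if d not in (-1, 0, 1):
            raise ValidationError(f"{label} direction for '{sig}' must be in {{-1,0,+1}}")


@dataclass(frozen=True)
class _Structure:
    """Gene/probe/signature scaffolding shared by paired studies."""

    gene_ids: np.ndarray
    probe_gene_idx: np.ndarray  # per probe: index into gene_ids
    probe_ids: np.ndarray
    signatures: SignatureSet
    sig_of_gene: np.ndarray  # per gene: signature index, -1 if none


def _build_structure(config: SimulationConfig, rng: np.random.Generator) -> _Structure:
    gene_ids = np.array([f"G{i:05d}" for i in range(1, config.n_genes + 1)])
    if isinstance(config.probes_per_gene, tuple):
        lo, hi = config.probes_per_gene
        ppg = rng.integers(lo, hi + 1, size=config.n_genes)
    else:
        ppg = np.full(config.n_genes, config.probes_per_gene, dtype=int)
    probe_gene_idx = np.repeat(np.arange(config.n_genes), ppg)
    probe_ids = np.array([f"P{i:06d}" for i in range(1, probe_gene_idx.size + 1)])

    order = rng.permutation(config.n_genes)
    sig_of_gene = np.full(config.n_genes, -1, dtype=int)
    sigs: dict[str, tuple[str, ...]] = {}
    gps = config.genes_per_signature
    for s in range(config.n_signatures):
        if config.allow_signature_overlap:
            members = rng.choice(config.n_genes, size=gps, replace=False)
        else:
            members = order[s * gps:(s + 1) * gps]
        # with overlap enabled a gene keeps its first signature for truth effects
        fresh = members[sig_of_gene[members] == -1]
        sig_of_gene[fresh] = s
        sigs[signature_name(s + 1)] = tuple(gene_ids[np.sort(members)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sigset = SignatureSet(sigs, {n: "synthetic signature" for n in sigs})
    return _Structure(gene_ids, probe_gene_idx, probe_ids, sigset, sig_of_gene)


def _condition_groups(config: SimulationConfig) -> tuple[list[Condition], dict[str, str]]:
    """Manifest conditions and the group -> compound map."""
    conditions: list[Condition] = []
    compound_of: dict[str, str] = {}
    for compound in config.compound_names():
        for j in range(1, config.conditions_per_compound + 1):
            group = f"{compound}_c{j}"
            compound_of[group] = compound
            conditions.append(Condition(
                compound=compound,
                dose=f"{10 * j} mg/kg",
                dose_value=float(10 * j),
                dose_unit="mg/kg",
                duration_value=float(j),
                duration_unit="days",
                treated_group=group,
                control_group=CONTROL_GROUP,
            ))
    return conditions, compound_of


def _generate_values(
    structure: _Structure,
    config: SimulationConfig,
    group_of_sample: dict[str, str],
    effects: Mapping[str, Mapping[str, int]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Probe x sample matrix: gene baseline + planted effect + noise."""
    sig_index = {name: i for i, name in enumerate(structure.signatures.names())}
    n_probes = structure.probe_ids.size
    samples = list(group_of_sample)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    base_probe = baseline[structure.probe_gene_idx]

    effect_by_group: dict[str, np.ndarray] = {}
    for group in dict.fromkeys(group_of_sample.values()):
        dir_by_sig = np.zeros(len(sig_index) + 1)
        for sig, d in effects.get(group, {}).items():
            dir_by_sig[sig_index[sig]] = d
        per_gene = dir_by_sig[structure.sig_of_gene]  # -1 hits the trailing 0
        effect_by_group[group] = config.effect_size * per_gene[structure.probe_gene_idx]

    noise = rng.normal(0.0, config.noise_sd, (n_probes, len(samples)))
    cols = {
        s: base_probe + effect_by_group[group_of_sample[s]] + noise[:, i]
        for i, s in enumerate(samples)
    }
    return pd.DataFrame(cols, index=structure.probe_ids)


def _study_from_parts(structure: _Structure, values: pd.DataFrame,
                      group_of_sample: dict[str, str],
                      control_of: dict[str, str]) -> ExpressionStudy:
    probe_gene = pd.Series(structure.gene_ids[structure.probe_gene_idx],
                           index=structure.probe_ids)
    return ExpressionStudy(
        values=values,
        probe_gene=probe_gene,
        groups=pd.Series(group_of_sample),
        control_of=control_of,
    )


@dataclass(frozen=True)
class SimulationResult:
    study: ExpressionStudy
    manifest: ConditionManifest
    signatures: SignatureSet
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Generate one expression study with the configured compound layout.

    Mimetic compounds receive ``mimetic_directions`` in all their treated
    groups, decoy compounds ``decoy_directions``; every other group has no
    planted effect.  Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_values = (np.random.default_rng(s) for s in ss.spawn(2))
    structure = _build_structure(config, rng_struct)
    conditions, compound_of = _condition_groups(config)

    group_of_sample: dict[str, str] = {
        f"{CONTROL_GROUP}_r{i}": CONTROL_GROUP for i in range(1, config.n_control + 1)
    }
    control_of: dict[str, str] = {}
    effects: dict[str, dict[str, int]] = {}
    for cond in conditions:
        group = cond.treated_group
        control_of[group] = CONTROL_GROUP
        for i in range(1, config.n_treated + 1):
            group_of_sample[f"{group}_r{i}"] = group
        compound = compound_of[group]
        if compound in config.mimetic_compounds:
            effects[group] = dict(config.mimetic_directions)
        elif compound in config.decoy_compounds:
            effects[group] = dict(config.decoy_directions)

    values = _generate_values(structure, config, group_of_sample, effects, rng_values)
    study = _study_from_parts(structure, values, group_of_sample, control_of)
    truth = GroundTruth(
        directions={
            g: {s: effects.get(g, {}).get(s, 0) for s in structure.signatures.names()}
            for g in dict.fromkeys(group_of_sample.values())
        },
        mimetics={c: c in config.mimetic_compounds for c in config.compound_names()},
    )
    return SimulationResult(study, ConditionManifest(conditions),
                            structure.signatures, truth)


@dataclass(frozen=True)
class BaitProbePair:
    """An independent bait study plus a compound-probe study over shared
    genes, probes and signatures."""

    bait_study: ExpressionStudy
    probe_study: ExpressionStudy
    manifest: ConditionManifest
    signatures: SignatureSet
    truth: GroundTruth
    bait_group: str


def simulate_bait_and_probe(
    config: SimulationConfig,
    bait_directions: Mapping[str, int],
    n_bait_samples: int | None = None,
) -> BaitProbePair:
    """Generate a bait study and an independent compound-probe study.

    The bait study has one treated group (``CR``) planted with
    ``bait_directions``.  In the probe study, compounds listed in
    ``config.mimetic_compounds`` receive the same direction map; decoy
    compounds receive ``config.decoy_directions``; the rest are noise.
    Gene/probe/signature structure is shared, baselines and noise are drawn
    independently per study.
    """
    config.validate()
    bait_directions = dict(bait_directions)
    _validate_directions(bait_directions, set(config.signature_names()), "bait")
    if n_bait_samples is None:
        n_bait_samples = config.n_treated
    if n_bait_samples < 1:
        raise ValidationError("n_bait_samples must be >= 1")

    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_bait, rng_probe = (np.random.default_rng(s) for s in ss.spawn(3))
    structure = _build_structure(config, rng_struct)

    # bait study: one treated group vs its own controls
    bait_groups = {
        f"{CONTROL_GROUP}_r{i}": CONTROL_GROUP for i in range(1, config.n_control + 1)
    }
    bait_groups.update({f"{BAIT_GROUP}_r{i}": BAIT_GROUP
                        for i in range(1, n_bait_samples + 1)})
    bait_effects = {BAIT_GROUP: dict(bait_directions)}
    bait_values = _generate_values(structure, config, bait_groups, bait_effects, rng_bait)
    bait_study = _study_from_parts(structure, bait_values, bait_groups,
                                   {BAIT_GROUP: CONTROL_GROUP})

    # probe study: the compound screen, mimetics planted with the bait map
    conditions, compound_of = _condition_groups(config)
    probe_groups: dict[str, str] = {
        f"{CONTROL_GROUP}_r{i}": CONTROL_GROUP for i in range(1, config.n_control + 1)
    }
    control_of: dict[str, str] = {}
    probe_effects: dict[str, dict[str, int]] = {}
    for cond in conditions:
        group = cond.treated_group
        control_of[group] = CONTROL_GROUP
        for i in range(1, config.n_treated + 1):
            probe_groups[f"{group}_r{i}"] = group
        compound = compound_of[group]
        if compound in config.mimetic_compounds:
            probe_effects[group] = dict(bait_directions)
        elif compound in config.decoy_compounds:
            probe_effects[group] = dict(config.decoy_directions)
    probe_values = _generate_values(structure, config, probe_groups, probe_effects,
                                    rng_probe)
    probe_study = _study_from_parts(structure, probe_values, probe_groups, control_of)

    sig_names = structure.signatures.names()
    directions = {
        BAIT_GROUP: {s: bait_directions.get(s, 0) for s in sig_names},
    }
    for g in dict.fromkeys(probe_groups.values()):
        directions[g] = {s: probe_effects.get(g, {}).get(s, 0) for s in sig_names}
    truth = GroundTruth(
        directions=directions,
        mimetics={c: c in config.mimetic_compounds for c in config.compound_names()},
    )
    return BaitProbePair(bait_study, probe_study, ConditionManifest(conditions),
                         structure.signatures, truth, BAIT_GROUP)
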