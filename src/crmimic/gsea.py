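"""Per-sample gene-set enrichment scoring with a gene-assignment permutation null.

For each treated sample, probes are ranked by the log2 difference between
the sample and the mean of its control group.  For each signature, the
classic enrichment running sum is evaluated over the ranked probe list: at
a hit (a probe whose gene belongs to the signature) it increases by
``|score|^p`` normalized by the sum of that quantity over all hits; at a
miss it decreases by ``1/(N - Nh)``.  The positive score ES+ is the
maximum positive deviation of the running sum, the negative score ES- the
minimum negative deviation; both are one-sided extremes of the same walk,
so ES+ >= 0 >= ES- always.

Significance comes from permuting the probe -> gene assignment: gene
labels are shuffled uniformly over the probes while the probe scores and
their ranking stay fixed.  Because a uniform relabeling places the
signature's labels on a uniformly random size-``Nh`` subset of rank
positions, the null is sampled by drawing random hit-position subsets,
which is what the implementation does.  P-values use the add-one
correction ``(1 + exceedances) / (1 + n_perm)`` and are therefore never 0.

A sample is called +1 (red, induced) for a signature when the positive
score is significant, -1 (blue, repressed) when the negative score is
significant, 0 (black) otherwise; if both sides are significant the side
with the strictly smaller p-value wins and an exact tie is called 0.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    SignatureNotRepresentedError,
    ValidationError,
)
from .io import ExpressionStudy, SignatureSet, UNANNOTATED, normalize_gene
from .records import EnrichmentResult, SignatureCallProfile

log = logging.getLogger(__name__)

#: Internal chunk size for vectorized permutation batches.  Fixed so that a
#: given (seed, n_perm) always consumes the random stream identically.
_PERM_CHUNK = 2048

#: Absolute tolerance when counting permutation extremes against the
#: observed score, guarding against last-ulp asymmetries at exact ties.
_TIE_TOL = 1e-12

DEFAULT_N_PERM = 100_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RankedProfile:
    """One treated sample's probes ordered by log2 difference vs control mean.

    Sorted by score descending; ties broken by probe id ascending so the
    order is deterministic across platforms.
    """

    sample: str
    probe_ids: np.ndarray
    scores: np.ndarray
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.probe_ids)


def rank_sample(study: ExpressionStudy, sample: str) -> RankedProfile:
    """Rank a treated sample's probes by (sample value - control-group mean).

    Probes missing in the sample or in every control sample are excluded
    and counted.  Errors if the sample's control group cannot be resolved
    or fewer than half the probes are usable.
    """
    if study.groups is None:
        raise ValidationError("study has no group assignments")
    if sample not in study.values.columns:
        raise ValidationError(f"sample '{sample}' not in expression matrix")
    group = study.groups[sample]
    control = study.control_of.get(group)
    if control is None:
        raise ValidationError(
            f"sample '{sample}' belongs to group '{group}' which names no control group"
        )
    control_samples = study.samples_in_group(control)
    if len(control_samples) < 2:
        raise ValidationError(
            f"control group '{control}' has {len(control_samples)} sample(s); >= 2 required"
        )
    diff = study.values[sample] - study.values[control_samples].mean(axis=1)
    usable = diff.notna()
    n_total = len(diff)
    if int(usable.sum()) < 0.5 * n_total:
        raise DegenerateSampleError(
            f"sample '{sample}': only {int(usable.sum())}/{n_total} probes usable"
        )
    d = diff[usable]
    # stable sort on a probe-id-sorted frame implements the tie rule
    d = d.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")
    return RankedProfile(
        sample=sample,
        probe_ids=d.index.to_numpy(dtype=str),
        scores=d.to_numpy(dtype=float),
        n_excluded=n_total - int(usable.sum()),
    )


def _as_probe_gene_series(probe_gene_map: Mapping[str, str] | pd.Series) -> pd.Series:
    if isinstance(probe_gene_map, pd.Series):
        return probe_gene_map
    return pd.Series(dict(probe_gene_map))


def hit_mask(
    ranked: RankedProfile,
    signature_genes: Iterable[str],
    probe_gene_map: Mapping[str, str] | pd.Series,
) -> np.ndarray:
    """Boolean mask over the ranked list: probe's gene is in the signature."""
    genes = {normalize_gene(g) for g in signature_genes}
    genes.discard(UNANNOTATED.upper())
    pg = _as_probe_gene_series(probe_gene_map).reindex(ranked.probe_ids)
    return pg.isin(genes).to_numpy()


def _weights(scores: np.ndarray, hits: np.ndarray, weight_exponent: float,
             signature: str = "") -> np.ndarray:
    """Per-probe hit-weight basis |score|^p, with the zero-weight fallback."""
    if weight_exponent not in (0, 1):
        raise ValidationError(f"weight_exponent must be 0 or 1, got {weight_exponent}")
    if weight_exponent == 0:
        return np.ones_like(scores)
    w = np.abs(scores)
    if w[hits].sum() == 0.0:
        log.warning(
            "all hit weights zero under exponent 1%s; falling back to exponent 0",
            f" for signature '{signature}'" if signature else "",
        )
        return np.ones_like(scores)
    return w


def _extremes_from_hits(hits_sorted: np.ndarray, w_full: np.ndarray,
                        n_probes: int) -> tuple[np.ndarray, np.ndarray]:
    """(ES+, ES-) for each row of sorted hit positions.

    The running sum is piecewise linear between hits, so its maximum is
    attained immediately after some hit and its minimum immediately before
    some hit (or at the endpoints, where it is 0).
    """
    k = hits_sorted.shape[1]
    m = 1.0 / (n_probes - k)
    w = w_full[hits_sorted]
    cw = np.cumsum(w, axis=1)
    total = cw[:, -1]
    zero = total <= 0.0
    if zero.any():
        # permuted hit set carries zero total weight: uniform increments
        w = w.copy()
        w[zero] = 1.0
        cw[zero] = np.cumsum(w[zero], axis=1)
        total = np.where(zero, float(k), total)
    idx = np.arange(1, k + 1)
    after = cw / total[:, None] - (hits_sorted + 1 - idx) * m
    before = (cw - w) / total[:, None] - (hits_sorted - idx + 1) * m
    es_pos = np.maximum(after.max(axis=1), 0.0)
    es_neg = np.minimum(before.min(axis=1), 0.0)
    return es_pos, es_neg


def _check_hit_count(k: int, n_probes: int, signature: str = "") -> None:
    label = f"signature '{signature}'" if signature else "signature"
    if k == 0:
        raise SignatureNotRepresentedError(
            f"{label} has no probes in the ranked list"
        )
    if k >= n_probes:
        raise ValidationError(
            f"{label} hits every probe; the miss decrement 1/(N - Nh) is undefined"
        )


def enrichment_scores(
    ranked: RankedProfile,
    signature_genes: Iterable[str],
    probe_gene_map: Mapping[str, str] | pd.Series,
    weight_exponent: float = 1,
) -> tuple[float, float]:
    """Running-sum enrichment scores (ES+, ES-) of a signature in a ranked list.

    With ``weight_exponent`` 1 (default) hit increments are proportional to
    |score|; with 0 they are uniform 1/Nh.  Misses always decrement by
    1/(N - Nh).
    """
    hits = hit_mask(ranked, signature_genes, probe_gene_map)
    k = int(hits.sum())
    _check_hit_count(k, len(ranked))
    w_full = _weights(ranked.scores, hits, weight_exponent)
    positions = np.flatnonzero(hits)[None, :]
    es_pos, es_neg = _extremes_from_hits(positions, w_full, len(ranked))
    return float(es_pos[0]), float(es_neg[0])


def _null_extremes(w_full: np.ndarray, k: int, n_perm: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Null (ES+, ES-) for ``n_perm`` uniform random hit-position subsets."""
    n_probes = w_full.size
    es_pos = np.empty(n_perm)
    es_neg = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(_PERM_CHUNK, n_perm - done)
        keys = rng.random((b, n_probes))
        hits = np.argpartition(keys, k - 1, axis=1)[:, :k]
        hits.sort(axis=1)
        p, n = _extremes_from_hits(hits, w_full, n_probes)
        es_pos[done:done + b] = p
        es_neg[done:done + b] = n
        done += b
    return es_pos, es_neg


def _pvalues_from_null(
    obs_pos: float, obs_neg: float,
    null_pos: np.ndarray, null_neg: np.ndarray,
) -> tuple[float, float]:
    n_perm = null_pos.size
    p_pos = (1 + int((null_pos >= obs_pos - _TIE_TOL).sum())) / (1 + n_perm)
    p_neg = (1 + int((null_neg <= obs_neg + _TIE_TOL).sum())) / (1 + n_perm)
    return p_pos, p_neg


def permutation_pvalues(
    ranked: RankedProfile,
    signature_genes: Iterable[str],
    probe_gene_map: Mapping[str, str] | pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = 0,
    weight_exponent: float = 1,
) -> tuple[float, float]:
    """Monte-Carlo p-values for (ES+, ES-) under gene-assignment permutation.

    ``p_pos = (1 + #{ES+_perm >= ES+_obs}) / (1 + n_perm)`` and analogously
    for the negative side with ``<=``.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    hits = hit_mask(ranked, signature_genes, probe_gene_map)
    k = int(hits.sum())
    _check_hit_count(k, len(ranked))
    w_full = _weights(ranked.scores, hits, weight_exponent)
    positions = np.flatnonzero(hits)[None, :]
    obs_pos, obs_neg = _extremes_from_hits(positions, w_full, len(ranked))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_pos, null_neg = _null_extremes(w_full, k, n_perm, rng)
    return _pvalues_from_null(float(obs_pos[0]), float(obs_neg[0]), null_pos, null_neg)


def call_signature(result: EnrichmentResult, alpha: float = DEFAULT_ALPHA) -> int:
    """Ternary call from a pair of permutation p-values."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return _call(result.p_pos, result.p_neg, alpha)


def _call(p_pos: float, p_neg: float, alpha: float) -> int:
    pos_sig = p_pos <= alpha
    neg_sig = p_neg <= alpha
    if pos_sig and (not neg_sig or p_pos < p_neg):
        return 1
    if neg_sig and (not pos_sig or p_neg < p_pos):
        return -1
    return 0


def _pair_rng(master_seed: int, *labels: str) -> np.random.Generator:
    """Independent, platform-stable random stream for a labelled pair.

    Streams are pre-assigned from the master seed by hashing the labels, so
    results do not depend on execution order and parallel scoring would
    reproduce serial results bit for bit.
    """
    digest = hashlib.sha256("\x1f".join(labels).encode("utf8")).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *words])
    return np.random.default_rng(ss)


@dataclass
class ScoreResult:
    """Profiles for every treated sample that scored, plus per-sample failures."""

    profiles: list[SignatureCallProfile]
    failures: dict[str, str] = field(default_factory=dict)


def score_study(
    study: ExpressionStudy,
    signatures: SignatureSet,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    weight_exponent: float = 1,
    seed: int = 0,
    null_sharing: str = "signature",
) -> ScoreResult:
    """Score every treated sample against every signature.

    ``null_sharing`` controls how permutation streams are organized:

    * ``"signature"`` (default): one independent stream per
      (sample, signature) pair;
    * ``"sample"``: signatures of a sample that share the same hit count
      reuse one stream of permutations.  The null distribution of the
      enrichment extremes depends only on the sample's score vector and the
      hit count, so the shared null is drawn from exactly the same
      distribution; sharing only introduces correlation between the
      Monte-Carlo errors of different signatures of the same sample.  Use
      it to score large synthetic screens at a fraction of the cost.

    Per-sample failures (degenerate samples, unresolvable controls) are
    collected in the result; the call raises only if every treated sample
    fails.  A signature with no mapped probes yields call 0 with flag
    ``not_represented``; one that hits every probe yields flag
    ``degenerate``.
    """
    if null_sharing not in ("signature", "sample"):
        raise ValidationError(f"null_sharing must be 'signature' or 'sample', got '{null_sharing}'")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")

    treated = study.treated_samples()
    profiles: list[SignatureCallProfile] = []
    failures: dict[str, str] = {}
    for sample in treated:
        try:
            ranked = rank_sample(study, sample)
        except (DegenerateSampleError, ValidationError) as exc:
            failures[sample] = str(exc)
            continue
        n_probes = len(ranked)
        pg = _as_probe_gene_series(study.probe_gene).reindex(ranked.probe_ids)
        base_w = (np.abs(ranked.scores) if weight_exponent == 1
                  else np.ones_like(ranked.scores))
        shared_nulls: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        results: list[EnrichmentResult] = []
        for name in signatures.names():
            genes = {normalize_gene(g) for g in signatures.genes(name)}
            genes.discard(UNANNOTATED.upper())
            hits = pg.isin(genes).to_numpy()
            k = int(hits.sum())
            if k == 0:
                results.append(EnrichmentResult(name, 0.0, 0.0, 1.0, 1.0, n_perm, 0,
                                                flag="not_represented"))
                continue
            if k >= n_probes:
                results.append(EnrichmentResult(name, 0.0, 0.0, 1.0, 1.0, n_perm, 0,
                                                flag="degenerate"))
                continue
            fallback = weight_exponent == 1 and base_w[hits].sum() == 0.0
            w_full = np.ones_like(base_w) if fallback else base_w
            positions = np.flatnonzero(hits)[None, :]
            obs_pos, obs_neg = _extremes_from_hits(positions, w_full, n_probes)
            if null_sharing == "sample" and not fallback:
                if k not in shared_nulls:
                    rng = _pair_rng(seed, sample, f"__shared_k={k}")
                    shared_nulls[k] = _null_extremes(w_full, k, n_perm, rng)
                null_pos, null_neg = shared_nulls[k]
            else:
                rng = _pair_rng(seed, sample, name)
                null_pos, null_neg = _null_extremes(w_full, k, n_perm, rng)
            p_pos, p_neg = _pvalues_from_null(float(obs_pos[0]), float(obs_neg[0]),
                                              null_pos, null_neg)
            call = _call(p_pos, p_neg, alpha)
            flag = "ok" if not fallback else "weight_fallback"
            results.append(EnrichmentResult(name, float(obs_pos[0]), float(obs_neg[0]),
                                            p_pos, p_neg, n_perm, call, flag=flag))
        profiles.append(SignatureCallProfile(sample=sample, results=tuple(results)))
    if treated and not profiles:
        raise ValidationError(
            "all treated samples failed to score: "
            + "; ".join(f"{s}: {msg}" for s, msg in failures.items())
        )
    if failures:
        log.warning("%d sample(s) failed to score: %s", len(failures), sorted(failures))
    return ScoreResult(profiles=profiles, failures=failures)
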