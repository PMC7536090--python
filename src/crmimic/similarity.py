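"""Cross-group similarity of ternary signature-call profiles.

Two samples are compared at the red/black/blue level: the Pearson
correlation of their ternary vectors (entered as integers -1/0/+1, no rank
transform).  Two groups are compared by computing that correlation for all
|bait| x |probe| sample pairings and summarizing the list with its 5%, 50%
and 95% empirical quantiles.  A condition is a positive hit when the 5%
quantile is strictly positive.

Pearson correlation is undefined for a constant (all-black) vector; such
pairings are assigned the value 0 (no evidence of similarity) and counted
separately, rather than dropped, because dropping them would bias the 5%
quantile optimistically.

Quantiles use the nearest-rank (lower) convention: the smallest value
whose cumulative fraction is >= q.  On small lists this is exact and
conservative for the hit rule.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .records import SignatureCallProfile, SimilaritySummary

QUANTILE_METHOD = "nearest_rank_lower"


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank (lower) empirical quantile: smallest value with
    cumulative fraction >= q."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValidationError("cannot take a quantile of an empty list")
    if not (0.0 <= q <= 1.0):
        raise ValidationError(f"quantile level must be in [0, 1], got {q}")
    idx = max(math.ceil(q * v.size), 1) - 1
    return float(v[min(idx, v.size - 1)])


def _validate_ternary(v: np.ndarray, label: str) -> None:
    if not np.isin(v, (-1, 0, 1)).all():
        raise ValidationError(f"{label}: entries must be in {{-1, 0, +1}}")


def ternary_pcc(x: Sequence[int], y: Sequence[int]) -> float:
    """Pearson correlation of two ternary vectors; 0.0 if either is constant."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.ndim != 1 or xa.size < 2:
        raise ValidationError("ternary vectors must be 1-D with length >= 2")
    _validate_ternary(xa, "x")
    _validate_ternary(ya, "y")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return 0.0
    r = np.corrcoef(xa, ya)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def pairwise_pcc_matrix(
    bait: Sequence[SignatureCallProfile],
    probe: Sequence[SignatureCallProfile],
) -> tuple[np.ndarray, int]:
    """All pairwise ternary correlations; degenerate pairings set to 0.

    Returns the |bait| x |probe| correlation matrix and the number of
    degenerate (constant-vector) pairings.
    """
    if not bait or not probe:
        raise ValidationError("both groups must be non-empty")
    order = bait[0].signature_names
    if len(order) < 2:
        raise ValidationError("profiles must cover >= 2 signatures")
    for p in (*bait, *probe):
        if p.signature_names != order:
            raise ValidationError(
                f"signature order mismatch for sample '{p.sample}'"
            )
    a = np.array([p.ternary for p in bait], dtype=float)
    b = np.array([p.ternary for p in probe], dtype=float)
    const_a = np.ptp(a, axis=1) == 0
    const_b = np.ptp(b, axis=1) == 0
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac ** 2).sum(axis=1))
    nb = np.sqrt((bc ** 2).sum(axis=1))
    na[const_a] = 1.0
    nb[const_b] = 1.0
    corr = (ac @ bc.T) / np.outer(na, nb)
    corr[const_a, :] = 0.0
    corr[:, const_b] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    n_degenerate = len(bait) * len(probe) - int((~const_a).sum()) * int((~const_b).sum())
    return corr, n_degenerate


def group_similarity(
    bait: Sequence[SignatureCallProfile],
    probe: Sequence[SignatureCallProfile],
    bait_id: str = "bait",
    probe_id: str = "probe",
) -> SimilaritySummary:
    """Quantile summary of all pairwise correlations between two groups."""
    corr, n_degenerate = pairwise_pcc_matrix(bait, probe)
    values = corr.ravel()
    return SimilaritySummary(
        bait_group=bait_id,
        probe_group=probe_id,
        n_pairings=values.size,
        q05=nearest_rank_quantile(values, 0.05),
        q50=nearest_rank_quantile(values, 0.50),
        q95=nearest_rank_quantile(values, 0.95),
        n_degenerate=n_degenerate,
    )


def is_positive_hit(summary: SimilaritySummary) -> bool:
    """A condition is a positive hit iff its 5% correlation quantile is
    strictly positive."""
    return summary.q05 > 0.0
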