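"""Compound-level hit calling by hypergeometric enrichment of positive conditions.

Each (compound, dose, duration) condition is an independent test: it is
positive when the 5% quantile of its pairwise correlations with the bait
group is strictly positive.  A compound is a hit when its number of
positive conditions is significantly enriched given the number of
conditions it was tested in, the total number of conditions, and the total
number of positive conditions — an upper hypergeometric tail, computed by
exact integer summation.

Vehicle conditions (compound name in a configurable vehicle list) are
excluded from both the totals and the per-compound records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

from .errors import ValidationError
from .io import ConditionManifest
from .records import CompoundHitRecord, Condition, SimilaritySummary
from .similarity import is_positive_hit

DEFAULT_SCREEN_ALPHA = 0.05


def hypergeom_tail(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N population, K successes, n draws).

    Exact summation over the upper tail using integer binomials; no
    normal approximation.
    """
    for name, v in (("x", x), ("n", n), ("K", K), ("N", N)):
        if int(v) != v:
            raise ValidationError(f"{name} must be an integer, got {v}")
    x, n, K, N = int(x), int(n), int(K), int(N)
    if not (0 <= x <= n <= N):
        raise ValidationError(f"need 0 <= x <= n <= N, got x={x}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if x > K:
        raise ValidationError(f"need x <= K, got x={x}, K={K}")
    lo = max(x, n - (N - K))
    hi = min(n, K)
    numer = sum(comb(K, j) * comb(N - K, n - j) for j in range(lo, hi + 1))
    return numer / comb(N, n)


@dataclass(frozen=True)
class ScreenResult:
    """Hit table plus the screen-level bookkeeping needed to audit it."""

    records: tuple[CompoundHitRecord, ...]
    excluded_conditions: tuple[Condition, ...]
    vehicle_conditions: tuple[Condition, ...]
    n_total: int
    k_total: int
    screen_alpha: float
    bh_corrected: bool
    bait_id: str

    def hits(self) -> list[CompoundHitRecord]:
        return [r for r in self.records if r.hit]


def screen_compounds(
    summaries: Sequence[SimilaritySummary],
    manifest: ConditionManifest,
    screen_alpha: float = DEFAULT_SCREEN_ALPHA,
    vehicles: Sequence[str] = (),
    bh: bool = False,
    bait_id: str = "bait",
) -> ScreenResult:
    """Aggregate per-condition hit calls into compound-level hits.

    ``summaries`` must each map (via their probe group) to exactly one
    manifest condition.  Manifest conditions without a summary are listed
    in the exclusions report, never silently dropped.  With ``bh=True``
    the hit flag uses Benjamini-Hochberg adjusted p-values (off by
    default: the raw per-compound hypergeometric p is the screen's
    decision statistic).
    """
    if not (0.0 < screen_alpha < 1.0):
        raise ValidationError(f"screen_alpha must be in (0, 1), got {screen_alpha}")
    cond_by_group = manifest.by_treated_group()
    summary_by_group: dict[str, SimilaritySummary] = {}
    for s in summaries:
        if s.probe_group not in cond_by_group:
            raise ValidationError(
                f"similarity summary for probe group '{s.probe_group}' matches "
                "no manifest condition"
            )
        if s.probe_group in summary_by_group:
            raise ValidationError(
                f"multiple similarity summaries for probe group '{s.probe_group}'"
            )
        summary_by_group[s.probe_group] = s

    vehicle_names = {v.strip().lower() for v in vehicles}
    excluded: list[Condition] = []
    vehicle_conds: list[Condition] = []
    tested: list[tuple[Condition, bool]] = []
    for cond in manifest.conditions:
        if cond.treated_group not in summary_by_group:
            excluded.append(cond)
            continue
        if cond.compound.strip().lower() in vehicle_names:
            vehicle_conds.append(cond)
            continue
        tested.append((cond, is_positive_hit(summary_by_group[cond.treated_group])))

    n_total = len(tested)
    k_total = sum(pos for _, pos in tested)
    per_compound: dict[str, list[bool]] = {}
    for cond, pos in tested:
        per_compound.setdefault(cond.compound, []).append(pos)

    compounds = sorted(per_compound)
    pvals = []
    counts = []
    for compound in compounds:
        flags = per_compound[compound]
        n, x = len(flags), sum(flags)
        counts.append((n, x))
        pvals.append(hypergeom_tail(x, n, k_total, n_total))

    if bh and compounds:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=screen_alpha, method="fdr_bh")
        hit_flags = list(reject)
    else:
        hit_flags = [p <= screen_alpha for p in pvals]

    records = [
        CompoundHitRecord(
            compound=compound,
            n_conditions=n,
            n_positive=x,
            p_hyper=p,
            hit=bool(h),
            bait_id=bait_id,
        )
        for compound, (n, x), p, h in zip(compounds, counts, pvals, hit_flags)
    ]
    records.sort(key=lambda r: (r.p_hyper, r.compound))
    return ScreenResult(
        records=tuple(records),
        excluded_conditions=tuple(excluded),
        vehicle_conditions=tuple(vehicle_conds),
        n_total=n_total,
        k_total=k_total,
        screen_alpha=screen_alpha,
        bh_corrected=bh,
        bait_id=bait_id,
    )
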