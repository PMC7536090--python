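"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written in plain Python (loops,
itertools, hand Pearson) so that agreement with the vectorized library
code is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Sequence

TIE_TOL = 1e-12


def running_sum_extremes(
    scores: Sequence[float],
    hit_positions: Sequence[int],
    weight_exponent: float,
) -> tuple[float, float]:
    """(ES+, ES-) by stepping through the ranked list one probe at a time."""
    n = len(scores)
    hits = set(hit_positions)
    k = len(hits)
    assert 0 < k < n
    miss = 1.0 / (n - k)
    if weight_exponent == 0:
        weights = {i: 1.0 for i in hits}
    else:
        weights = {i: abs(scores[i]) ** weight_exponent for i in hits}
        if sum(weights.values()) == 0.0:
            weights = {i: 1.0 for i in hits}
    total = sum(weights.values())
    run = 0.0
    hi = 0.0
    lo = 0.0
    for i in range(n):
        if i in hits:
            run += weights[i] / total
        else:
            run -= miss
        hi = max(hi, run)
        lo = min(lo, run)
    return hi, lo


def exhaustive_permutation_pvalues(
    scores: Sequence[float],
    observed_hits: Sequence[int],
    weight_exponent: float,
) -> tuple[float, float]:
    """Exact null tail probabilities by enumerating every hit-position subset.

    A uniform shuffle of the gene labels over probes places the signature's
    labels on a uniformly random size-k subset of rank positions, so the
    exact null is the uniform distribution over all C(N, k) subsets.
    """
    k = len(observed_hits)
    obs_pos, obs_neg = running_sum_extremes(scores, observed_hits, weight_exponent)
    n_ge = n_le = total = 0
    for subset in combinations(range(len(scores)), k):
        es_pos, es_neg = running_sum_extremes(scores, subset, weight_exponent)
        n_ge += es_pos >= obs_pos - TIE_TOL
        n_le += es_neg <= obs_neg + TIE_TOL
        total += 1
    return n_ge / total, n_le / total


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def bruteforce_group_quantiles(
    bait_vectors: Sequence[Sequence[int]],
    probe_vectors: Sequence[Sequence[int]],
) -> tuple[float, float, float, int]:
    """Explicit double loop + nearest-rank sort indexing; degenerate pairs -> 0."""
    values = []
    n_degenerate = 0
    for x in bait_vectors:
        for y in probe_vectors:
            if len(set(x)) == 1 or len(set(y)) == 1:
                values.append(0.0)
                n_degenerate += 1
            else:
                values.append(pearson(x, y))
    values.sort()
    n = len(values)

    def q(level: float) -> float:
        return values[max(math.ceil(level * n), 1) - 1]

    return q(0.05), q(0.50), q(0.95), n_degenerate


def bruteforce_hypergeom_tail(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) by enumerating every size-n draw from a labelled population."""
    population = [1] * K + [0] * (N - K)
    total = at_least = 0
    for draw in combinations(range(N), n):
        total += 1
        at_least += sum(population[i] for i in draw) >= x
    return at_least / total
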