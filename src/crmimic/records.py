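"""Result containers shared across pipeline stages.

These are plain frozen dataclasses so that every stage's output can be
serialized to TSV by :mod:`crmimic.io` and reconstructed losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one signature in one treated sample.

    ``es_pos``/``es_neg`` are the maximum positive and minimum negative
    deviations of the enrichment running sum (each one-sided, so
    ``es_pos >= 0 >= es_neg``).  ``p_pos``/``p_neg`` are Monte-Carlo
    permutation p-values with the add-one correction, hence in (0, 1].
    ``call`` is the ternary significance call: +1 induced (red),
    0 no change (black), -1 repressed (blue).
    """

    signature: str
    es_pos: float
    es_neg: float
    p_pos: float
    p_neg: float
    n_permutations: int
    call: int
    flag: str = "ok"

    def __post_init__(self):
        if self.es_pos < 0 or self.es_neg > 0:
            raise ValidationError(
                f"{self.signature}: es_pos must be >= 0 and es_neg <= 0 "
                f"(got {self.es_pos}, {self.es_neg})"
            )
        for name, p in (("p_pos", self.p_pos), ("p_neg", self.p_neg)):
            if not (0.0 < p <= 1.0):
                raise ValidationError(f"{self.signature}: {name}={p} outside (0, 1]")
        if self.call not in (-1, 0, 1):
            raise ValidationError(f"{self.signature}: call must be in {{-1,0,1}}")


@dataclass(frozen=True)
class SignatureCallProfile:
    """All signature enrichment results for one treated sample, fixed order."""

    sample: str
    results: tuple[EnrichmentResult, ...]

    @property
    def signature_names(self) -> tuple[str, ...]:
        return tuple(r.signature for r in self.results)

    @property
    def ternary(self) -> np.ndarray:
        """Ternary red/black/blue vector as int8 (+1 / 0 / -1)."""
        return np.array([r.call for r in self.results], dtype=np.int8)


@dataclass(frozen=True)
class SimilaritySummary:
    """Quantile summary of all pairwise ternary-profile correlations
    between a bait group and a probe group.

    ``n_pairings`` counts every (bait sample, probe sample) pairing;
    pairings where either profile is constant are assigned correlation 0
    and counted in ``n_degenerate``.
    """

    bait_group: str
    probe_group: str
    n_pairings: int
    q05: float
    q50: float
    q95: float
    n_degenerate: int = 0

    def __post_init__(self):
        if not (self.q05 <= self.q50 <= self.q95):
            raise ValidationError(
                f"quantiles out of order for ({self.bait_group}, {self.probe_group}): "
                f"{self.q05}, {self.q50}, {self.q95}"
            )
        for q in (self.q05, self.q50, self.q95):
            if not (-1.0 - 1e-12 <= q <= 1.0 + 1e-12):
                raise ValidationError(f"correlation quantile {q} outside [-1, 1]")
        if self.n_degenerate > self.n_pairings:
            raise ValidationError("n_degenerate exceeds n_pairings")


@dataclass(frozen=True)
class CompoundHitRecord:
    """Compound-level hypergeometric enrichment of positive conditions."""

    compound: str
    n_conditions: int
    n_positive: int
    p_hyper: float
    hit: bool
    bait_id: str

    def __post_init__(self):
        if not (0 <= self.n_positive <= self.n_conditions):
            raise ValidationError(
                f"{self.compound}: n_positive={self.n_positive} outside "
                f"[0, {self.n_conditions}]"
            )
        if not (0.0 < self.p_hyper <= 1.0):
            raise ValidationError(f"{self.compound}: p_hyper={self.p_hyper} outside (0, 1]")


@dataclass(frozen=True)
class Condition:
    """One (compound, dose, duration) treatment condition and its groups."""

    compound: str
    dose: str
    dose_value: float
    dose_unit: str
    duration_value: float
    duration_unit: str
    treated_group: str
    control_group: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.compound, self.dose, f"{self.duration_value:g} {self.duration_unit}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth emitted by the synthetic-data generator.

    ``directions`` maps group -> signature -> planted direction in
    {+1, 0, -1}; ``mimetics`` maps compound -> whether it was planted with
    the bait's direction map.
    """

    directions: dict[str, dict[str, int]] = field(default_factory=dict)
    mimetics: dict[str, bool] = field(default_factory=dict)

    def direction(self, group: str, signature: str) -> int:
        return self.directions.get(group, {}).get(signature, 0)
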