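"""Readers and writers for every pipeline input and output.

Inputs
------
* gene signatures: GMT (``name<TAB>description<TAB>gene...``);
* expression data: plain TSV (probe x sample matrix, two-column probe map,
  three-column sample group map) or the GEO series-matrix text dialect
  (matrix block only; the group map is always supplied separately);
* condition manifests: TSV, one row per (compound, dose, duration).

Outputs
-------
Profile, similarity, hit and ground-truth tables, all TSV.  Floats are
written with 17 significant digits so a write/read round trip is
bit-identical.

Gene identifiers are matched by exact string comparison after uppercasing
and whitespace stripping; cross-species symbol mapping must happen
upstream.  Probes with no gene annotation receive the reserved
``unannotated`` token: they stay in the ranked background but can never be
signature hits (the permutation null shuffles gene labels over a fixed
probe universe, so the universe must not shrink).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .records import (
    CompoundHitRecord,
    Condition,
    EnrichmentResult,
    GroundTruth,
    SignatureCallProfile,
    SimilaritySummary,
)

log = logging.getLogger(__name__)

#: Reserved gene token for probes without annotation.  Gene symbols are
#: normalized to upper case, so the lower-case token can never collide.
UNANNOTATED = "unannotated"

_FLOAT_FMT = "%.17g"


def normalize_gene(gene: str) -> str:
    """Canonical gene identifier: stripped and uppercased."""
    return gene.strip().upper()


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


@dataclass
class SignatureSet:
    """Ordered collection of named gene lists used as enrichment queries."""

    signatures: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.signatures.items():
            if len(genes) == 0:
                raise ValidationError(f"signature '{name}' has no genes")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"signature '{name}' contains duplicate genes")
            if len(genes) < 5:
                warnings.warn(
                    f"signature '{name}' has only {len(genes)} gene(s); "
                    "enrichment on very small sets is unstable",
                    stacklevel=2,
                )

    def names(self) -> tuple[str, ...]:
        return tuple(self.signatures)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.signatures[name]

    def subset(self, names: Iterable[str]) -> "SignatureSet":
        names = list(names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return SignatureSet(
                {n: self.signatures[n] for n in names},
                {n: self.descriptions.get(n, "") for n in names},
            )

    def __len__(self) -> int:
        return len(self.signatures)

    def __contains__(self, name: str) -> bool:
        return name in self.signatures


def read_gmt(path: str | Path) -> SignatureSet:
    """Read a GMT signature file.

    Each non-blank line must have at least three tab-separated fields:
    name, description, then one or more genes.  Duplicate genes within a
    line are collapsed (first occurrence kept); a duplicate signature name
    is an error.  An empty file yields an empty set with a warning.
    """
    path = Path(path)
    signatures: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            if name in signatures:
                raise ParseError(f"{path}: line {lineno}: duplicate signature name '{name}'")
            seen: dict[str, None] = {}
            for g in fields[2:]:
                g = normalize_gene(g)
                if g:
                    seen.setdefault(g, None)
            if not seen:
                raise ParseError(f"{path}: line {lineno}: signature '{name}' has no genes")
            signatures[name] = tuple(seen)
            descriptions[name] = fields[1].strip()
    if not signatures:
        warnings.warn(f"{path}: GMT file contains no signatures", stacklevel=2)
    return SignatureSet(signatures, descriptions)


def write_gmt(sigset: SignatureSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf8") as fh:
        for name in sigset.names():
            desc = sigset.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sigset.genes(name)]) + "\n")


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """Probe x sample log2 expression matrix with annotations.

    ``values``: probes (rows) x samples (columns), float, log2 scale.
    ``probe_gene``: probe -> normalized gene symbol (``unannotated`` allowed).
    ``groups``: sample -> group id, or None when not yet assigned (as after
    reading a bare series-matrix file).
    ``control_of``: treated group -> its control group.
    """

    values: pd.DataFrame
    probe_gene: pd.Series
    groups: pd.Series | None = None
    control_of: dict[str, str] = field(default_factory=dict)
    sample_titles: dict[str, str] = field(default_factory=dict)
    n_missing: int = 0

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe identifiers: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers in matrix")
        missing_probes = self.values.index.difference(self.probe_gene.index)
        if len(missing_probes):
            raise ValidationError(
                f"{len(missing_probes)} probes lack a probe->gene entry "
                "(assign the 'unannotated' token explicitly)"
            )
        self.probe_gene = (
            self.probe_gene.reindex(self.values.index)
            .astype(str)
            .map(lambda g: g if g == UNANNOTATED else normalize_gene(g))
        )
        self.n_missing = int(self.values.isna().sum().sum())
        if self.n_missing:
            log.warning("expression matrix contains %d missing cells", self.n_missing)
        if self.groups is not None:
            absent = [s for s in self.values.columns if s not in self.groups.index]
            if absent:
                raise ValidationError(f"samples missing from group map: {absent}")
            self.groups = self.groups.reindex(self.values.columns)
            sizes = self.groups.value_counts()
            for treated, control in self.control_of.items():
                if control not in sizes.index:
                    raise ValidationError(
                        f"treated group '{treated}' names control group "
                        f"'{control}' which has no samples"
                    )
                if sizes[control] < 2:
                    raise ValidationError(
                        f"control group '{control}' has {sizes[control]} sample(s); "
                        ">= 2 required"
                    )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValidationError("study has no group assignments")
        return list(self.groups.index[self.groups == group])

    def treated_samples(self) -> list[str]:
        """Samples in groups that name a control group, in column order."""
        if self.groups is None:
            raise ValidationError("study has no group assignments")
        return [s for s in self.values.columns if self.groups[s] in self.control_of]

    def with_annotations(
        self,
        probe_gene: Mapping[str, str] | pd.Series,
        groups: Mapping[str, str] | pd.Series,
        control_of: Mapping[str, str],
    ) -> "ExpressionStudy":
        """Return a copy with probe map and group assignments attached."""
        pg = _coerce_probe_map(pd.Series(dict(probe_gene)), self.values.index)
        return ExpressionStudy(
            values=self.values,
            probe_gene=pg,
            groups=pd.Series(dict(groups)),
            control_of=dict(control_of),
            sample_titles=dict(self.sample_titles),
        )


def _coerce_probe_map(raw: pd.Series, probes: pd.Index) -> pd.Series:
    """Normalize genes, fill unannotated probes, log coverage."""
    pg = raw.astype(str).map(normalize_gene)
    pg = pg.reindex(probes)
    n_unannotated = int(pg.isna().sum())
    if n_unannotated:
        log.info("%d probes without gene annotation -> '%s'", n_unannotated, UNANNOTATED)
    return pg.fillna(UNANNOTATED)


def read_expression_tsv(
    matrix_path: str | Path,
    probe_map_path: str | Path,
    groups_path: str | Path,
) -> ExpressionStudy:
    """Read a plain-TSV expression study.

    ``matrix_path``: header row of sample ids, first column probe ids.
    ``probe_map_path``: two columns ``probe<TAB>gene`` (header row required).
    ``groups_path``: three columns ``sample<TAB>group<TAB>control_group``
    (header row required; blank control_group for control groups).

    Probes absent from the probe map receive the ``unannotated`` token (a
    count is logged).  A matrix sample missing from the groups file, or a
    non-numeric cell, is an error naming the offending coordinates.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & raw.notna() & (raw.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{matrix_path}: non-numeric value '{raw.iat[r, c]}' at "
            f"probe '{raw.index[r]}', sample '{raw.columns[c]}'"
        )
    # second pass with the exact parser so written values round-trip bit-identically
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    values = values.astype(float)

    pm = pd.read_csv(probe_map_path, sep="\t", dtype=str)
    if pm.shape[1] < 2:
        raise ParseError(f"{probe_map_path}: expected two columns (probe, gene)")
    pm = pm.iloc[:, :2]
    pm.columns = ["probe", "gene"]
    dup = pm["probe"].duplicated()
    if dup.any():
        log.warning(
            "%d probes map to multiple genes; keeping the first mapping for each",
            int(dup.sum()),
        )
        pm = pm[~dup]
    probe_gene = _coerce_probe_map(pm.set_index("probe")["gene"], values.index)

    gr = pd.read_csv(groups_path, sep="\t", dtype=str, keep_default_na=False)
    if gr.shape[1] < 3:
        raise ParseError(
            f"{groups_path}: expected three columns (sample, group, control_group)"
        )
    gr = gr.iloc[:, :3]
    gr.columns = ["sample", "group", "control_group"]
    groups = gr.set_index("sample")["group"]
    control_of: dict[str, str] = {}
    for _, row in gr.iterrows():
        ctrl = row["control_group"].strip()
        if ctrl:
            prev = control_of.get(row["group"])
            if prev is not None and prev != ctrl:
                raise ParseError(
                    f"{groups_path}: group '{row['group']}' names two control "
                    f"groups ('{prev}', '{ctrl}')"
                )
            control_of[row["group"]] = ctrl
    return ExpressionStudy(values=values, probe_gene=probe_gene, groups=groups,
                           control_of=control_of)


def read_series_matrix(
    path: str | Path,
    transform: str = "none",
    log2_threshold: float = 30.0,
) -> ExpressionStudy:
    """Read the matrix block of a GEO series-matrix text file.

    Values are assumed to be on the log2 scale already (the convention for
    RMA-summarized deposits).  With ``transform="auto"``, ``log2(x + 1)``
    is applied — and logged — when the matrix maximum exceeds
    ``log2_threshold``, a heuristic for linear-scale deposits.  Nothing is
    ever transformed silently.

    The returned study has no group assignments and an all-``unannotated``
    probe map; attach both with :meth:`ExpressionStudy.with_annotations`.
    Sample titles from ``!Sample_title`` lines are kept for manual group
    assignment.
    """
    if transform not in ("none", "auto"):
        raise ValidationError(f"transform must be 'none' or 'auto', got '{transform}'")
    path = Path(path)
    titles: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, encoding="utf8") as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(stripped)
            elif stripped.startswith("!Sample_title"):
                titles = [t.strip().strip('"') for t in stripped.split("\t")[1:]]
    if not (saw_begin and saw_end):
        raise ParseError(
            f"{path}: missing series_matrix_table_begin/_end delimiters"
        )
    if not table_lines:
        raise ParseError(f"{path}: empty series-matrix table")
    from io import StringIO

    values = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index = [str(i).strip('"') for i in values.index]
    values.columns = [str(c).strip('"') for c in values.columns]
    values = values.apply(lambda c: pd.to_numeric(c, errors="coerce")
                          if c.dtype == object else c)
    if transform == "auto":
        vmax = float(np.nanmax(values.to_numpy()))
        if vmax > log2_threshold:
            log.warning(
                "series matrix maximum %.3g exceeds %.3g; applying log2(x + 1)",
                vmax, log2_threshold,
            )
            values = np.log2(values + 1.0)
    sample_titles = dict(zip(values.columns, titles)) if len(titles) == len(values.columns) else {}
    probe_gene = pd.Series(UNANNOTATED, index=values.index)
    return ExpressionStudy(values=values, probe_gene=probe_gene,
                           sample_titles=sample_titles)


def write_expression_tsv(
    study: ExpressionStudy,
    matrix_path: str | Path,
    probe_map_path: str | Path,
    groups_path: str | Path,
) -> None:
    study.values.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT,
                        index_label="probe")
    study.probe_gene.rename("gene").to_csv(probe_map_path, sep="\t", index_label="probe")
    if study.groups is None:
        raise ValidationError("cannot write groups: study has no group assignments")
    gr = pd.DataFrame(
        {
            "sample": study.groups.index,
            "group": study.groups.values,
            "control_group": [study.control_of.get(g, "") for g in study.groups.values],
        }
    )
    gr.to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# condition manifests
# ---------------------------------------------------------------------------


@dataclass
class ConditionManifest:
    """Condition records mapping treatment groups to compounds/doses/durations."""

    conditions: list[Condition]

    def __post_init__(self):
        keys = [c.key for c in self.conditions]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dupes = []
            for k in keys:
                if k in seen:
                    dupes.append(k)
                seen.add(k)
            raise ValidationError(
                f"duplicate (compound, dose, duration) condition(s): {dupes[:3]}"
            )

    def validate_against(self, study: ExpressionStudy) -> None:
        if study.groups is None:
            raise ValidationError("study has no group assignments")
        groups = set(study.groups.unique())
        for c in self.conditions:
            for g in (c.treated_group, c.control_group):
                if g not in groups:
                    raise ValidationError(
                        f"condition {c.key}: group '{g}' not present in study"
                    )

    def by_treated_group(self) -> dict[str, Condition]:
        out: dict[str, Condition] = {}
        for c in self.conditions:
            if c.treated_group in out:
                raise ValidationError(
                    f"treated group '{c.treated_group}' appears in more than one condition"
                )
            out[c.treated_group] = c
        return out

    def __len__(self) -> int:
        return len(self.conditions)


_MANIFEST_COLS = [
    "compound", "dose", "dose_value", "dose_unit",
    "duration_value", "duration_unit", "treated_group", "control_group",
]


def read_condition_manifest(path: str | Path) -> ConditionManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    conditions = [
        Condition(
            compound=row["compound"],
            dose=row["dose"],
            dose_value=float(row["dose_value"]),
            dose_unit=row["dose_unit"],
            duration_value=float(row["duration_value"]),
            duration_unit=row["duration_unit"],
            treated_group=row["treated_group"],
            control_group=row["control_group"],
        )
        for _, row in df.iterrows()
    ]
    return ConditionManifest(conditions)


def write_condition_manifest(manifest: ConditionManifest, path: str | Path) -> None:
    df = pd.DataFrame([
        {
            "compound": c.compound,
            "dose": c.dose,
            "dose_value": c.dose_value,
            "dose_unit": c.dose_unit,
            "duration_value": c.duration_value,
            "duration_unit": c.duration_unit,
            "treated_group": c.treated_group,
            "control_group": c.control_group,
        }
        for c in manifest.conditions
    ], columns=_MANIFEST_COLS)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_PROFILE_COLS = ["sample", "signature", "es_pos", "es_neg", "p_pos", "p_neg",
                 "n_permutations", "call", "flag"]


def write_profile_table(
    profiles: Sequence[SignatureCallProfile], path: str | Path
) -> None:
    """Write signature call profiles as TSV, one row per (sample, signature).

    Rows follow input order: samples in given order, signatures in profile
    order.  Floats use 17 significant digits so the round trip is exact.
    """
    rows = [
        {
            "sample": p.sample,
            "signature": r.signature,
            "es_pos": r.es_pos,
            "es_neg": r.es_neg,
            "p_pos": r.p_pos,
            "p_neg": r.p_neg,
            "n_permutations": r.n_permutations,
            "call": r.call,
            "flag": r.flag,
        }
        for p in profiles
        for r in p.results
    ]
    pd.DataFrame(rows, columns=_PROFILE_COLS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_profile_table(path: str | Path) -> list[SignatureCallProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "signature": str, "flag": str},
                     float_precision="round_trip")
    missing = [c for c in _PROFILE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: profile table missing columns {missing}")
    profiles: list[SignatureCallProfile] = []
    for sample in df["sample"].unique():
        sub = df[df["sample"] == sample]
        results = tuple(
            EnrichmentResult(
                signature=row["signature"],
                es_pos=float(row["es_pos"]),
                es_neg=float(row["es_neg"]),
                p_pos=float(row["p_pos"]),
                p_neg=float(row["p_neg"]),
                n_permutations=int(row["n_permutations"]),
                call=int(row["call"]),
                flag=str(row["flag"]),
            )
            for _, row in sub.iterrows()
        )
        profiles.append(SignatureCallProfile(sample=str(sample), results=results))
    return profiles


def write_ternary_matrix(profiles: Sequence[SignatureCallProfile],
                         path: str | Path) -> None:
    """Sample x signature matrix of ternary calls, ordered for heatmap
    rendering (samples as rows in input order, signatures as columns)."""
    if not profiles:
        raise ValidationError("cannot export an empty profile collection")
    order = profiles[0].signature_names
    df = pd.DataFrame(
        [p.ternary for p in profiles],
        index=[p.sample for p in profiles],
        columns=list(order),
    )
    df.to_csv(path, sep="\t", index_label="sample")


_SIMILARITY_COLS = ["bait_group", "probe_group", "n_pairings", "q05", "q50", "q95",
                    "n_degenerate", "quantile_method"]


def write_similarity_table(
    summaries: Sequence[SimilaritySummary],
    path: str | Path,
    quantile_method: str = "nearest_rank_lower",
) -> None:
    rows = [
        {
            "bait_group": s.bait_group,
            "probe_group": s.probe_group,
            "n_pairings": s.n_pairings,
            "q05": s.q05,
            "q50": s.q50,
            "q95": s.q95,
            "n_degenerate": s.n_degenerate,
            "quantile_method": quantile_method,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=_SIMILARITY_COLS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_similarity_table(path: str | Path) -> list[SimilaritySummary]:
    df = pd.read_csv(path, sep="\t", dtype={"bait_group": str, "probe_group": str},
                     float_precision="round_trip")
    return [
        SimilaritySummary(
            bait_group=str(row["bait_group"]),
            probe_group=str(row["probe_group"]),
            n_pairings=int(row["n_pairings"]),
            q05=float(row["q05"]),
            q50=float(row["q50"]),
            q95=float(row["q95"]),
            n_degenerate=int(row["n_degenerate"]),
        )
        for _, row in df.iterrows()
    ]


_HIT_COLS = ["compound", "n_conditions", "n_positive", "p_hyper", "hit", "bait_id"]


def write_hit_table(records: Sequence[CompoundHitRecord], path: str | Path,
                    meta: Mapping[str, object] | None = None) -> None:
    """Write the compound hit table; screen-level metadata goes into
    ``#``-prefixed header comment lines."""
    with open(path, "w", encoding="utf8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        pd.DataFrame([
            {
                "compound": r.compound,
                "n_conditions": r.n_conditions,
                "n_positive": r.n_positive,
                "p_hyper": r.p_hyper,
                "hit": int(r.hit),
                "bait_id": r.bait_id,
            }
            for r in records
        ], columns=_HIT_COLS).to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_hit_table(path: str | Path) -> list[CompoundHitRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"compound": str, "bait_id": str},
                     float_precision="round_trip")
    return [
        CompoundHitRecord(
            compound=str(row["compound"]),
            n_conditions=int(row["n_conditions"]),
            n_positive=int(row["n_positive"]),
            p_hyper=float(row["p_hyper"]),
            hit=bool(int(row["hit"])),
            bait_id=str(row["bait_id"]),
        )
        for _, row in df.iterrows()
    ]


def write_ground_truth(truth: GroundTruth, directions_path: str | Path,
                       compounds_path: str | Path) -> None:
    rows = [
        {"group": g, "signature": s, "direction": d}
        for g, sigmap in truth.directions.items()
        for s, d in sigmap.items()
    ]
    pd.DataFrame(rows, columns=["group", "signature", "direction"]).to_csv(
        directions_path, sep="\t", index=False
    )
    pd.DataFrame(
        [{"compound": c, "mimetic": int(m)} for c, m in truth.mimetics.items()],
        columns=["compound", "mimetic"],
    ).to_csv(compounds_path, sep="\t", index=False)


def read_ground_truth(directions_path: str | Path,
                      compounds_path: str | Path) -> GroundTruth:
    ddf = pd.read_csv(directions_path, sep="\t", dtype={"group": str, "signature": str})
    directions: dict[str, dict[str, int]] = {}
    for _, row in ddf.iterrows():
        directions.setdefault(str(row["group"]), {})[str(row["signature"])] = int(row["direction"])
    cdf = pd.read_csv(compounds_path, sep="\t", dtype={"compound": str})
    mimetics = {str(row["compound"]): bool(int(row["mimetic"])) for _, row in cdf.iterrows()}
    return GroundTruth(directions=directions, mimetics=mimetics)
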