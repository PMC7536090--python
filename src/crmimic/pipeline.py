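"""End-to-end orchestration: simulate/load -> score -> match -> screen.

A run is driven by a :class:`RunConfig`, loadable from a flat
``key = value`` text file.  Every output is TSV; a ``run_manifest.json``
records all parameters, the seed, the package version and per-stage counts
so any output can be reproduced exactly.  A stage failure leaves partial
outputs in place together with a ``RUN.partial`` marker naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .errors import StageError, ValidationError
from .gsea import DEFAULT_ALPHA, DEFAULT_N_PERM, score_study
from .io import (
    ConditionManifest,
    ExpressionStudy,
    SignatureSet,
    read_condition_manifest,
    read_expression_tsv,
    read_gmt,
    write_condition_manifest,
    write_expression_tsv,
    write_gmt,
    write_ground_truth,
    write_hit_table,
    write_profile_table,
    write_similarity_table,
)
from .records import SignatureCallProfile, SimilaritySummary
from .screen import DEFAULT_SCREEN_ALPHA, ScreenResult, screen_compounds
from .similarity import QUANTILE_METHOD, group_similarity
from .simulate import SimulationConfig, simulate_bait_and_probe

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for a full bait-vs-probe screening run."""

    out_dir: Path
    seed: int = 0
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    screen_alpha: float = DEFAULT_SCREEN_ALPHA
    weight_exponent: float = 1
    null_sharing: str = "signature"
    vehicles: tuple[str, ...] = ()
    bh: bool = False
    mode: str = "simulate"
    # simulate mode
    sim: SimulationConfig | None = None
    bait_directions: dict[str, int] = field(default_factory=dict)
    n_bait_samples: int | None = None
    # files mode
    bait_matrix: Path | None = None
    bait_probe_map: Path | None = None
    bait_groups: Path | None = None
    bait_group: str = "CR"
    probe_matrix: Path | None = None
    probe_probe_map: Path | None = None
    probe_groups: Path | None = None
    manifest_path: Path | None = None
    signatures_path: Path | None = None

    def validate(self) -> None:
        for name, v in (("alpha", self.alpha), ("screen_alpha", self.screen_alpha)):
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.n_perm < 1:
            raise ValidationError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.weight_exponent not in (0, 1):
            raise ValidationError(f"weight_exponent must be 0 or 1, got {self.weight_exponent}")
        if self.null_sharing not in ("signature", "sample"):
            raise ValidationError(f"unknown null_sharing '{self.null_sharing}'")
        if self.mode == "simulate":
            if self.sim is None:
                raise ValidationError("simulate mode requires simulation parameters")
            self.sim.validate()
            if not self.bait_directions:
                raise ValidationError("simulate mode requires bait_directions")
        elif self.mode == "files":
            required = {
                "bait_matrix": self.bait_matrix,
                "bait_probe_map": self.bait_probe_map,
                "bait_groups": self.bait_groups,
                "probe_matrix": self.probe_matrix,
                "probe_probe_map": self.probe_probe_map,
                "probe_groups": self.probe_groups,
                "manifest_path": self.manifest_path,
                "signatures_path": self.signatures_path,
            }
            for name, p in required.items():
                if p is None:
                    raise ValidationError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ValidationError(f"{name}: no such file '{p}'")
        else:
            raise ValidationError(f"unknown mode '{self.mode}'")


def _parse_bait_directions(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise ValidationError(f"bait_directions entry '{item}' is not NAME:DIR")
        name, d = item.split(":", 1)
        out[name.strip()] = int(d)
    return out


def load_run_config(path: str | Path, out_dir: str | Path,
                    overrides: Mapping[str, str] | None = None) -> RunConfig:
    """Load a flat ``key = value`` run configuration.

    Simulation parameters use the ``sim_`` prefix (``sim_n_genes = 260``);
    ``bait_directions`` is a comma list of ``SIG:DIR`` entries; blank lines
    and ``#`` comments are ignored.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        raw[key.strip()] = value.strip()
    raw.update(overrides or {})

    def pop(key: str, default: str | None = None) -> str | None:
        return raw.pop(key, default)

    sim_keys = {k: v for k, v in list(raw.items()) if k.startswith("sim_")}
    for k in sim_keys:
        raw.pop(k)
    mode = pop("mode", "simulate")
    sim = None
    if sim_keys or mode == "simulate":
        kwargs: dict = {}
        for k, v in sim_keys.items():
            name = k[len("sim_"):]
            if name in ("mimetic_compounds", "decoy_compounds"):
                kwargs[name] = tuple(x.strip() for x in v.split(",") if x.strip())
            elif name in ("mimetic_directions", "decoy_directions"):
                kwargs[name] = _parse_bait_directions(v)
            elif name == "probes_per_gene":
                kwargs[name] = (tuple(int(x) for x in v.split("-"))
                                if "-" in v else int(v))
            elif name in ("baseline_mean", "baseline_sd", "noise_sd", "effect_size"):
                kwargs[name] = float(v)
            elif name == "allow_signature_overlap":
                kwargs[name] = v.lower() in ("1", "true", "yes")
            else:
                kwargs[name] = int(v)
        sim = SimulationConfig(**kwargs)

    seed = int(pop("seed", "0"))
    if sim is not None:
        sim = SimulationConfig(**{**sim.__dict__, "seed": seed})
    cfg = RunConfig(
        out_dir=Path(out_dir),
        seed=seed,
        n_perm=int(pop("n_perm", str(DEFAULT_N_PERM))),
        alpha=float(pop("alpha", str(DEFAULT_ALPHA))),
        screen_alpha=float(pop("screen_alpha", str(DEFAULT_SCREEN_ALPHA))),
        weight_exponent=float(pop("weight_exponent", "1")),
        null_sharing=pop("null_sharing", "signature"),
        vehicles=tuple(x.strip() for x in pop("vehicles", "").split(",") if x.strip()),
        bh=pop("bh", "false").lower() in ("1", "true", "yes"),
        mode=mode,
        sim=sim,
        bait_directions=_parse_bait_directions(pop("bait_directions", "")),
        n_bait_samples=(int(raw.pop("n_bait_samples")) if "n_bait_samples" in raw else None),
        bait_group=pop("bait_group", "CR"),
        **{
            name: (Path(raw.pop(name)) if name in raw else None)
            for name in ("bait_matrix", "bait_probe_map", "bait_groups",
                         "probe_matrix", "probe_probe_map", "probe_groups",
                         "manifest_path", "signatures_path")
        },
    )
    if raw:
        raise ValidationError(f"{path}: unknown configuration keys {sorted(raw)}")
    return cfg


@dataclass
class RunResult:
    paths: dict[str, Path]
    screen: ScreenResult
    manifest: dict


def match_groups(
    bait_profiles: list[SignatureCallProfile],
    probe_profiles: list[SignatureCallProfile],
    probe_study_groups: Mapping[str, str],
    manifest: ConditionManifest,
    bait_id: str,
) -> list[SimilaritySummary]:
    """One similarity summary per manifest condition that has scored profiles."""
    by_group: dict[str, list[SignatureCallProfile]] = {}
    for p in probe_profiles:
        by_group.setdefault(probe_study_groups[p.sample], []).append(p)
    summaries = []
    for cond in manifest.conditions:
        group_profiles = by_group.get(cond.treated_group)
        if group_profiles:
            summaries.append(group_similarity(bait_profiles, group_profiles,
                                              bait_id=bait_id,
                                              probe_id=cond.treated_group))
    return summaries


def run_pipeline(config: RunConfig) -> RunResult:
    """Run simulate/load -> score -> match -> screen, writing all result tables."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial_marker = out / "RUN.partial"
    paths: dict[str, Path] = {}
    counts: dict[str, object] = {}
    stage = "inputs"
    try:
        bait_study, probe_study, manifest, signatures, bait_group = _stage_inputs(
            config, out, paths
        )
        stage = "score"
        bait_scored = score_study(bait_study, signatures, n_perm=config.n_perm,
                                  alpha=config.alpha,
                                  weight_exponent=config.weight_exponent,
                                  seed=config.seed, null_sharing=config.null_sharing)
        probe_scored = score_study(probe_study, signatures, n_perm=config.n_perm,
                                   alpha=config.alpha,
                                   weight_exponent=config.weight_exponent,
                                   seed=config.seed, null_sharing=config.null_sharing)
        paths["bait_profiles"] = out / "bait_profiles.tsv"
        paths["probe_profiles"] = out / "probe_profiles.tsv"
        write_profile_table(bait_scored.profiles, paths["bait_profiles"])
        write_profile_table(probe_scored.profiles, paths["probe_profiles"])
        counts["bait_samples_scored"] = len(bait_scored.profiles)
        counts["probe_samples_scored"] = len(probe_scored.profiles)
        counts["score_failures"] = {**bait_scored.failures, **probe_scored.failures}
        log.info("scored %d bait and %d probe samples",
                 len(bait_scored.profiles), len(probe_scored.profiles))

        stage = "match"
        bait_profiles = [p for p in bait_scored.profiles
                         if bait_study.groups[p.sample] == bait_group]
        if not bait_profiles:
            raise ValidationError(f"no scored bait samples in group '{bait_group}'")
        summaries = match_groups(bait_profiles, probe_scored.profiles,
                                 probe_study.groups, manifest, bait_group)
        paths["similarity"] = out / "similarity.tsv"
        write_similarity_table(summaries, paths["similarity"],
                               quantile_method=QUANTILE_METHOD)
        counts["pairings_computed"] = int(sum(s.n_pairings for s in summaries))
        counts["conditions_matched"] = len(summaries)
        log.info("computed %d summaries (%d pairings)", len(summaries),
                 counts["pairings_computed"])

        stage = "screen"
        result = screen_compounds(summaries, manifest,
                                  screen_alpha=config.screen_alpha,
                                  vehicles=config.vehicles, bh=config.bh,
                                  bait_id=bait_group)
        paths["hits"] = out / "hits.tsv"
        write_hit_table(result.records, paths["hits"], meta={
            "bait_id": result.bait_id,
            "n_total_conditions": result.n_total,
            "k_total_positive": result.k_total,
            "screen_alpha": result.screen_alpha,
            "bh_corrected": result.bh_corrected,
            "n_excluded_conditions": len(result.excluded_conditions),
            "n_vehicle_conditions": len(result.vehicle_conditions),
        })
        counts["conditions_screened"] = result.n_total
        counts["positive_conditions"] = result.k_total
        counts["compound_hits"] = len(result.hits())
        log.info("screened %d conditions (%d positive): %d compound hit(s)",
                 result.n_total, result.k_total, len(result.hits()))

        stage = "manifest"
        manifest_doc = {
            "crmimic_version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "screen_alpha": config.screen_alpha,
            "weight_exponent": config.weight_exponent,
            "null_sharing": config.null_sharing,
            "quantile_method": QUANTILE_METHOD,
            "vehicles": list(config.vehicles),
            "bh": config.bh,
            "mode": config.mode,
            "bait_group": bait_group,
            "counts": counts,
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        if config.mode == "simulate":
            manifest_doc["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in config.sim.__dict__.items()
                if not isinstance(v, dict)
            }
            manifest_doc["bait_directions"] = config.bait_directions
        paths["run_manifest"] = out / "run_manifest.json"
        paths["run_manifest"].write_text(json.dumps(manifest_doc, indent=2, sort_keys=True))
    except Exception as exc:
        partial_marker.write_text(f"failed at stage: {stage}\n{exc}\n")
        raise StageError(stage, exc) from exc
    if partial_marker.exists():
        partial_marker.unlink()
    return RunResult(paths=paths, screen=result, manifest=manifest_doc)


def _stage_inputs(config: RunConfig, out: Path, paths: dict[str, Path]):
    if config.mode == "simulate":
        pair = simulate_bait_and_probe(config.sim, config.bait_directions,
                                       n_bait_samples=config.n_bait_samples)
        data = out / "data"
        data.mkdir(exist_ok=True)
        write_expression_tsv(pair.bait_study, data / "bait_matrix.tsv",
                             data / "bait_probe_map.tsv", data / "bait_groups.tsv")
        write_expression_tsv(pair.probe_study, data / "probe_matrix.tsv",
                             data / "probe_probe_map.tsv", data / "probe_groups.tsv")
        write_condition_manifest(pair.manifest, data / "manifest.tsv")
        write_gmt(pair.signatures, data / "signatures.gmt")
        write_ground_truth(pair.truth, data / "truth_directions.tsv",
                           data / "truth_compounds.tsv")
        paths["data_dir"] = data
        return (pair.bait_study, pair.probe_study, pair.manifest, pair.signatures,
                pair.bait_group)
    bait_study = read_expression_tsv(config.bait_matrix, config.bait_probe_map,
                                     config.bait_groups)
    probe_study = read_expression_tsv(config.probe_matrix, config.probe_probe_map,
                                      config.probe_groups)
    manifest = read_condition_manifest(config.manifest_path)
    manifest.validate_against(probe_study)
    signatures = read_gmt(config.signatures_path)
    return bait_study, probe_study, manifest, signatures, config.bait_group
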