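#!/usr/bin/env python
"""Generate the synthetic bait-vs-probe screen analysed by the later steps.

One calorie-restriction-like bait study (one treated group, planted with a
six-up/four-down signature direction map) and one compound probe study
(10 compounds x 4 dose/duration conditions, 2 planted mimetics sharing the
bait's direction map).  All tables are written under results/analysis/data/.
"""

from pathlib import Path

from crmimic.io import (
    write_condition_manifest,
    write_expression_tsv,
    write_gmt,
    write_ground_truth,
)
from crmimic.simulate import SimulationConfig, simulate_bait_and_probe

SEED = 7
DATA_DIR = Path(__file__).resolve().parents[1] / "results" / "analysis" / "data"

CONFIG = SimulationConfig(
    n_genes=260, probes_per_gene=(1, 3), n_signatures=20, genes_per_signature=10,
    noise_sd=0.25, effect_size=1.0, n_control=3, n_treated=2,
    n_compounds=10, conditions_per_compound=4,
    mimetic_compounds=("CPD_01", "CPD_02"), seed=SEED,
)
BAIT_DIRECTIONS = {
    **{f"SIG_{i:02d}": 1 for i in range(1, 7)},
    **{f"SIG_{i:02d}": -1 for i in range(7, 11)},
}


def main() -> None:
    pair = simulate_bait_and_probe(CONFIG, BAIT_DIRECTIONS, n_bait_samples=4)
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(pair.bait_study, DATA_DIR / "bait_matrix.tsv",
                         DATA_DIR / "bait_probe_map.tsv", DATA_DIR / "bait_groups.tsv")
    write_expression_tsv(pair.probe_study, DATA_DIR / "probe_matrix.tsv",
                         DATA_DIR / "probe_probe_map.tsv", DATA_DIR / "probe_groups.tsv")
    write_condition_manifest(pair.manifest, DATA_DIR / "manifest.tsv")
    write_gmt(pair.signatures, DATA_DIR / "signatures.gmt")
    write_ground_truth(pair.truth, DATA_DIR / "truth_directions.tsv",
                       DATA_DIR / "truth_compounds.tsv")
    n_conditions = len(pair.manifest)
    print(f"bait study: {len(pair.bait_study.samples)} samples "
          f"({len(pair.bait_study.samples_in_group(pair.bait_group))} in group "
          f"'{pair.bait_group}'), {len(pair.bait_study.probes)} probes")
    print(f"probe study: {len(pair.probe_study.samples)} samples, "
          f"{n_conditions} conditions over {CONFIG.n_compounds} compounds")
    print(f"planted mimetics: {', '.join(CONFIG.mimetic_compounds)}")
    print(f"data written to {DATA_DIR}")


if __name__ == "__main__":
    main()
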