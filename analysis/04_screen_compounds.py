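#!/usr/bin/env python
"""Call compound-level hits and compare them with the planted truth.

Aggregates the per-condition positive calls into a hypergeometric
enrichment test per compound and prints the hit table next to the
generator's ground truth.
"""

from pathlib import Path

from crmimic.io import read_condition_manifest, read_ground_truth, \
    read_similarity_table, write_hit_table
from crmimic.screen import screen_compounds

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
DATA = ROOT / "data"
BAIT_GROUP = "CR"


def main() -> None:
    summaries = read_similarity_table(ROOT / "similarity.tsv")
    manifest = read_condition_manifest(DATA / "manifest.tsv")
    truth = read_ground_truth(DATA / "truth_directions.tsv",
                              DATA / "truth_compounds.tsv")
    result = screen_compounds(summaries, manifest, screen_alpha=0.05,
                              bait_id=BAIT_GROUP)
    out = ROOT / "hits.tsv"
    write_hit_table(result.records, out, meta={
        "bait_id": result.bait_id,
        "n_total_conditions": result.n_total,
        "k_total_positive": result.k_total,
        "screen_alpha": result.screen_alpha,
    })
    print(f"screened {result.n_total} conditions, {result.k_total} positive")
    print(f"{'compound':<10}{'pos/tested':>12}{'p_hyper':>12}{'hit':>6}{'planted':>9}")
    for r in result.records:
        print(f"{r.compound:<10}{f'{r.n_positive}/{r.n_conditions}':>12}"
              f"{r.p_hyper:>12.4g}{str(r.hit):>6}"
              f"{str(truth.mimetics.get(r.compound, False)):>9}")
    hits = {r.compound for r in result.hits()}
    planted = {c for c, m in truth.mimetics.items() if m}
    print(f"\nrecovered {len(hits & planted)}/{len(planted)} planted mimetics, "
          f"{len(hits - planted)} false positive(s) -> {out}")


if __name__ == "__main__":
    main()
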