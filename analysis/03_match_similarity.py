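#!/usr/bin/env python
"""Match every compound condition against the bait profile group.

For each condition, the Pearson correlation of ternary profiles is
computed for all (bait sample, treated sample) pairings and summarized by
its 5%/50%/95% nearest-rank quantiles.  A condition whose 5% quantile is
strictly positive is a positive hit.
"""

from pathlib import Path

import pandas as pd

from crmimic.io import (
    read_condition_manifest,
    read_profile_table,
    write_similarity_table,
)
from crmimic.pipeline import match_groups
from crmimic.similarity import QUANTILE_METHOD, is_positive_hit

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
DATA = ROOT / "data"
BAIT_GROUP = "CR"


def main() -> None:
    bait = read_profile_table(ROOT / "bait_profiles.tsv")
    probe = read_profile_table(ROOT / "probe_profiles.tsv")
    bait_groups = pd.read_csv(DATA / "bait_groups.tsv", sep="\t",
                              dtype=str).set_index("sample")["group"]
    probe_groups = pd.read_csv(DATA / "probe_groups.tsv", sep="\t",
                               dtype=str).set_index("sample")["group"]
    bait_sel = [p for p in bait if bait_groups[p.sample] == BAIT_GROUP]
    manifest = read_condition_manifest(DATA / "manifest.tsv")
    summaries = match_groups(bait_sel, probe, probe_groups, manifest, BAIT_GROUP)
    out = ROOT / "similarity.tsv"
    write_similarity_table(summaries, out, quantile_method=QUANTILE_METHOD)
    n_pos = sum(is_positive_hit(s) for s in summaries)
    print(f"matched {len(bait_sel)} bait profiles against {len(summaries)} "
          f"conditions ({sum(s.n_pairings for s in summaries)} pairings)")
    print(f"{n_pos} positive condition(s) (5% quantile > 0) -> {out}")


if __name__ == "__main__":
    main()
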