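#!/usr/bin/env python
"""Merge donor models into subgroup networks and compare them.

Per-group mean edge activity with the upper-quartile active mask, Jaccard
distances of every donor to the healthy mean network against the all-pairs
background, and the differentially active interactions between healthy and
untreated.  Writes results/cohort/{subgroup_activity.csv,
subgroup_active_mask.csv, distance_report.csv, distance_summary.csv}.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from combilogic.pipeline import stage_merge, _load_models  # noqa: E402
from combilogic.subgroup import (differential_interactions,  # noqa: E402
                                 merge_subgroup)


def main() -> None:
    config = study_config()
    paths = stage_merge(config)
    summary = pd.read_csv(Path(OUTDIR) / "distance_summary.csv", index_col=0)
    print("median Jaccard distance to the healthy mean network, and rank-sum")
    print("p of each group's distances vs the all-pairs background:")
    print(summary.round(4).to_string())

    by_group, edge_ids = _load_models(config)
    nets = {g: merge_subgroup(list(ms.values()), g, edge_ids)
            for g, ms in by_group.items()}
    parts = differential_interactions(nets["healthy"], nets["untreated"])
    print(f"\nhealthy-only active: {sorted(map(str, parts['a_only']))}")
    print(f"untreated-only active: {sorted(map(str, parts['b_only']))}")
    print(f"shared active: {sorted(map(str, parts['shared']))}")
    print("wrote:", ", ".join(p.name for p in paths))


if __name__ == "__main__":
    main()
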