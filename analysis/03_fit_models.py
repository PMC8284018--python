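#!/usr/bin/env python
"""Train one Boolean logic model per donor with the genetic algorithm.

Ten independent GA runs per donor; the donor model is the per-edge median
over the tolerance ensemble.  Writes results/cohort/{donor_weights.csv,
run_log.json} and prints per-group fit quality.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from combilogic.pipeline import stage_fit  # noqa: E402


def main() -> None:
    config = study_config()
    paths = stage_fit(config)
    weights = pd.read_csv(Path(OUTDIR) / "donor_weights.csv", index_col=0)
    summary = weights.groupby("group").agg(
        best_score=("best_score", "mean"),
        ensemble_size=("ensemble_size", "mean"))
    print("per-group fit summary (means over donors):")
    print(summary.round(4).to_string())
    edge_cols = [c for c in weights.columns
                 if c not in ("group", "best_score", "ensemble_size")]
    print(f"\n{len(weights)} donor models over {len(edge_cols)} candidate "
          f"hyperedges")
    print("wrote:", ", ".join(p.name for p in paths))


if __name__ == "__main__":
    main()
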