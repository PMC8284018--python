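#!/usr/bin/env python
"""Score co-druggability per treatment and predict combination targets.

For each treatment group: the per-interaction score
|S_healthy − S_MS| − |S_healthy − S_treatment| with the near-zero collapse,
upper-quartile difference and rank-sum significance filters; then the graph
search mapping each co-druggable interaction to (stimulus, readout) pairs
that can engage and report it.  Writes results/cohort/{codruggability.csv,
predictions.csv, interaction_summary.csv}.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from combilogic.pipeline import stage_codrug, stage_predict  # noqa: E402


def main() -> None:
    config = study_config()
    paths = stage_codrug(config) + stage_predict(config)
    records = pd.read_csv(Path(OUTDIR) / "codruggability.csv")
    flagged = records[records["co_druggable"]]
    cols = ["treatment", "interaction", "s_healthy", "s_ms", "s_treatment",
            "score", "p_value"]
    print("co-druggable interactions (per treatment):")
    print(flagged[cols].round(3).to_string(index=False))

    truth = json.loads((Path(OUTDIR) / "ground_truth.json").read_text())
    dereg = truth["deregulated_edges"]
    for t in sorted(set(flagged["treatment"])):
        planted = set(dereg[t]) & set(dereg["untreated"])
        found = set(flagged.loc[flagged["treatment"] == t, "interaction"])
        print(f"{t}: planted unreverted {sorted(planted)} -> "
              f"{len(planted & found)}/{len(planted)} flagged")

    preds = pd.read_csv(Path(OUTDIR) / "predictions.csv")
    print(f"\n{len(preds)} combination predictions "
          f"(stimulus x co-druggable interaction x readout):")
    if not preds.empty:
        print(preds.to_string(index=False))
    print("wrote:", ", ".join(p.name for p in paths))


if __name__ == "__main__":
    main()
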