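#!/usr/bin/env python
"""Confirm that subgroup models are reflected in the phospho-measurements.

Three stages: one-sample signed-rank test per (group, stimulus, readout)
with BH correction; model support by active-edge reachability; one-sided
Fisher enrichment of significant pairs among supported ones.  Writes
results/cohort/{confirmation_pairs.csv, confirmation_enrichment.csv}.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from combilogic.pipeline import stage_confirm  # noqa: E402


def main() -> None:
    config = study_config()
    paths = stage_confirm(config)
    enr = pd.read_csv(Path(OUTDIR) / "confirmation_enrichment.csv")
    print("per-group enrichment of responding pairs among model-supported")
    print("stimulus-readout pairs (one-sided Fisher exact):")
    print(enr.to_string(index=False))
    pairs = pd.read_csv(Path(OUTDIR) / "confirmation_pairs.csv")
    agree = (pairs["significant"] == pairs["model_supported"]).mean()
    print(f"\nstage-1/stage-2 agreement: {agree:.1%} of "
          f"{len(pairs)} (group, stimulus, readout) pairs")
    print("wrote:", ", ".join(p.name for p in paths))


if __name__ == "__main__":
    main()
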