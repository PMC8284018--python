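#!/usr/bin/env python
"""Normalize the raw MFI cohort for Boolean fitting.

Fold changes vs the media control, max-magnitude timepoint collapse, the
three-state significance filter (robust z vs control noise + BH within
donor) and the Hill transform to [0, 1].  Writes results/cohort/
{normalized.csv, state_percentages.csv, groups.csv} and prints the
per-readout state composition.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from combilogic.pipeline import stage_normalize  # noqa: E402


def main() -> None:
    config = study_config()
    paths = stage_normalize(config)
    pct = pd.read_csv(Path(OUTDIR) / "state_percentages.csv", index_col=0)
    print("per-readout classification (% of donor-stimulus pairs):")
    print(pct.round(1).to_string())
    table = pd.read_csv(Path(OUTDIR) / "normalized.csv")
    n_sig = table["value"].notna().sum()
    print(f"\n{n_sig} of {len(table)} (donor, stimulus, readout) triples "
          f"significant -> enter the fitting objective")
    print("wrote:", ", ".join(p.name for p in paths))


if __name__ == "__main__":
    main()
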