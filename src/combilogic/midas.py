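"""MIDAS-shaped perturbation datasets.

MIDAS is the tabular CSV convention for perturbation screens: per row one
(sample, condition, timepoint), with ``TR:`` treatment columns (0/1 flags for
each stimulus), ``DA:`` data-acquisition columns (the timepoint, minutes, one
per readout) and ``DV:`` data-value columns (the mean fluorescence intensity,
MFI, one per readout).  Donor identity and group label travel in ``ID:``
columns.

Internally the dataset is a tidy long :class:`pandas.DataFrame` with columns
``donor, group, stimulus, readout, time, value``; the control (media)
condition is encoded with the dataset's ``control_name`` in the stimulus
column and corresponds to an all-zero ``TR:`` block in MIDAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL_NAME = "media"

LONG_COLUMNS = ["donor", "group", "stimulus", "readout", "time", "value"]


@dataclass
class PerturbationDataset:
    """Tensor of MFI values over (donor, condition, readout, timepoint)."""

    data: pd.DataFrame
    control_name: str = CONTROL_NAME
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(LONG_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")

    # -- bookkeeping ------------------------------------------------------
    @property
    def donors(self) -> list[str]:
        return sorted(self.data["donor"].unique())

    @property
    def stimuli(self) -> list[str]:
        """Stimulus conditions, excluding the media control."""
        return sorted(set(self.data["stimulus"].unique()) - {self.control_name})

    @property
    def readouts(self) -> list[str]:
        return sorted(self.data["readout"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.data["time"].unique())

    @property
    def groups(self) -> dict[str, str]:
        """donor -> group label."""
        sub = self.data[["donor", "group"]].drop_duplicates()
        return dict(zip(sub["donor"], sub["group"]))

    @property
    def measurement_count(self) -> int:
        """Number of stimulus-condition measurements (control rows excluded)."""
        return int((self.data["stimulus"] != self.control_name).sum())

    # -- MIDAS I/O --------------------------------------------------------
    def to_midas(self, path) -> None:
        stimuli = self.stimuli
        readouts = self.readouts
        wide = self.data.pivot_table(
            index=["donor", "group", "stimulus", "time"],
            columns="readout", values="value", aggfunc="first").reset_index()
        out = pd.DataFrame({
            "ID:donor": wide["donor"],
            "ID:group": wide["group"],
        })
        for s in stimuli:
            out[f"TR:{s}"] = (wide["stimulus"] == s).astype(int)
        for r in readouts:
            out[f"DA:{r}"] = wide["time"]
        for r in readouts:
            out[f"DV:{r}"] = wide[r]
        out = out.sort_values(["ID:donor", "ID:group"] +
                              [f"TR:{s}" for s in stimuli] +
                              [f"DA:{readouts[0]}"]).reset_index(drop=True)
        out.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_midas(cls, path, control_name: str = CONTROL_NAME) -> "PerturbationDataset":
        wide = pd.read_csv(path)
        tr_cols = [c for c in wide.columns if c.startswith("TR:")]
        dv_cols = [c for c in wide.columns if c.startswith("DV:")]
        da_cols = [c for c in wide.columns if c.startswith("DA:")]
        if not dv_cols or not da_cols:
            raise ValueError(f"{path}: no DV:/DA: columns — not a MIDAS file")
        stimuli = [c[3:] for c in tr_cols]
        records = []
        for _, row in wide.iterrows():
            on = [s for s, c in zip(stimuli, tr_cols) if row[c] == 1]
            if len(on) > 1:
                raise ValueError(f"{path}: combinatorial TR rows not supported")
            stim = on[0] if on else control_name
            donor = row.get("ID:donor", "d0")
            group = row.get("ID:group", "all")
            for dv in dv_cols:
                readout = dv[3:]
                records.append((donor, group, stim, readout,
                                float(row[f"DA:{readout}"]), float(row[dv])))
        data = pd.DataFrame.from_records(records, columns=LONG_COLUMNS)
        return cls(data=data, control_name=control_name)

    def values_tensor(self) -> np.ndarray:
        """(donor, condition, readout, time) array, conditions = control + stimuli."""
        conditions = [self.control_name] + self.stimuli
        pivot = self.data.pivot_table(
            index=["donor", "stimulus"], columns=["readout", "time"],
            values="value", aggfunc="first")
        pivot = pivot.reindex(
            pd.MultiIndex.from_product([self.donors, conditions]))
        n_d, n_c = len(self.donors), len(conditions)
        n_r, n_t = len(self.readouts), len(self.timepoints)
        return pivot.to_numpy().reshape(n_d, n_c, n_r, n_t)
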