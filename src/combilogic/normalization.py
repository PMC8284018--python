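"""Normalization of raw MFI tensors to [0, 1] values for Boolean fitting.

The pipeline mirrors how single-replicate xMAP perturbation data is prepared
for logic modeling:

1. **Fold change** — per (donor, stimulus, readout, timepoint > 0), the log
   ratio of the stimulated MFI to the media control at the same timepoint.
2. **Timepoint collapse** — the 5- and 25-min fold changes are collapsed to
   the one of maximal absolute magnitude, sign preserved, so that late
   effects of motifs such as negative feedback loops are captured.
3. **Three-state significance filter** — a robust z-score against the
   per-readout spread of control-condition fold changes (1.4826 x MAD),
   two-sided normal p-values, Benjamini-Hochberg within donor; significant
   positives are *phosphorylated*, significant negatives *dephosphorylated*,
   the rest *non_significant* and excluded from the fitting objective.
4. **Hill normalization** — phosphorylated fold changes map through
   ``|fc|^k / (ec50^k + |fc|^k)`` to (0, 1), penalizing outliers;
   dephosphorylated observations are encoded as target value 0 so inhibitory
   logic is fittable; non-significant entries become missing.

The default half-effect point is half the donor's median positive |fc|: the
donor's typical significant response then maps to ~0.8, i.e., clearly toward
the active Boolean state, while staying adaptive to each donor's dynamic
range.  Pass an explicit ``ec50`` to override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .logic_fit import DonorData
from .midas import PerturbationDataset

PHOSPHORYLATED = "phosphorylated"
DEPHOSPHORYLATED = "dephosphorylated"
NON_SIGNIFICANT = "non_significant"

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


@dataclass
class NormalizationParams:
    ec50: float | None = None  # None: 0.5 x donor median positive |fc|
    hill_k: float = 2.0
    z_crit: float = 1.96  # used only when fdr_q is None (plain z threshold)
    fdr_q: float | None = 0.05

    def __post_init__(self) -> None:
        if self.ec50 is not None and self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_k <= 0 or self.z_crit <= 0:
            raise ValueError("hill_k and z_crit must be positive")
        if self.fdr_q is not None and not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass
class NormalizedDataset:
    """Per-(donor, stimulus, readout) normalized values and states."""

    table: pd.DataFrame  # donor, stimulus, readout, fc, z, p, q, state, value
    params: NormalizationParams
    meta: dict = field(default_factory=dict)

    def donor_data(self, donor: str, stimuli: list[str],
                   readouts: list[str]) -> DonorData:
        """Condition x readout value matrix for one donor (NaN = excluded)."""
        sub = self.table[self.table["donor"] == donor]
        pivot = sub.pivot_table(index="stimulus", columns="readout",
                                values="value", aggfunc="first")
        pivot = pivot.reindex(index=stimuli, columns=readouts)
        return DonorData(conditions=[frozenset([s]) for s in stimuli],
                         readouts=list(readouts),
                         values=pivot.to_numpy())

    def state_percentages(self) -> pd.DataFrame:
        """Per readout, the percentage of entries in each of the 3 states."""
        counts = (self.table.groupby(["readout", "state"]).size()
                  .unstack(fill_value=0))
        for col in (PHOSPHORYLATED, DEPHOSPHORYLATED, NON_SIGNIFICANT):
            if col not in counts:
                counts[col] = 0
        pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
        return pct[[PHOSPHORYLATED, DEPHOSPHORYLATED, NON_SIGNIFICANT]]


# ---------------------------------------------------------------------------
# Stage 1: fold changes
# ---------------------------------------------------------------------------

def _check_positive(data: pd.DataFrame) -> None:
    bad = data[data["value"] <= 0]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"nonpositive MFI at donor={row['donor']} stimulus={row['stimulus']} "
            f"readout={row['readout']} t={row['time']}: {row['value']}")


def fold_change(raw: PerturbationDataset) -> pd.DataFrame:
    """Signed log fold change vs the media control at matching timepoints.

    Returns a frame (donor, stimulus, readout, time, fc) for the stimulus
    conditions at t > 0; the baseline and control rows are consumed, not
    emitted.
    """
    _check_positive(raw.data)
    data = raw.data
    ctrl = data[(data["stimulus"] == raw.control_name) & (data["time"] > 0)]
    if ctrl.empty:
        raise ValueError("dataset has no control (media) condition at t > 0")
    ctrl = ctrl.rename(columns={"value": "control"})[
        ["donor", "readout", "time", "control"]]
    stim = data[(data["stimulus"] != raw.control_name) & (data["time"] > 0)]
    merged = stim.merge(ctrl, on=["donor", "readout", "time"], how="left")
    if merged["control"].isna().any():
        raise ValueError("missing control measurements for some timepoints")
    merged["fc"] = np.log(merged["value"] / merged["control"])
    return merged[["donor", "stimulus", "readout", "time", "fc"]]


def control_fold_change(raw: PerturbationDataset) -> pd.DataFrame:
    """Pure-noise fold changes: control at t > 0 vs control baseline."""
    _check_positive(raw.data)
    data = raw.data
    ctrl = data[data["stimulus"] == raw.control_name]
    base = ctrl[ctrl["time"] == 0].rename(columns={"value": "baseline"})[
        ["donor", "readout", "baseline"]]
    late = ctrl[ctrl["time"] > 0]
    merged = late.merge(base, on=["donor", "readout"], how="left")
    merged["fc"] = np.log(merged["value"] / merged["baseline"])
    return merged[["donor", "readout", "time", "fc"]]


def collapse_timepoints(fc: pd.DataFrame) -> pd.DataFrame:
    """Keep, per triple, the timepoint value of maximal |fc|, sign preserved."""
    fc = fc.dropna(subset=["fc"])
    idx = (fc.assign(absfc=fc["fc"].abs())
             .sort_values(["absfc", "time"])  # tie -> later timepoint, same value
             .groupby(["donor", "stimulus", "readout"], sort=True)
             .tail(1))
    return (idx[["donor", "stimulus", "readout", "fc"]]
            .sort_values(["donor", "stimulus", "readout"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Stage 2: significance filter
# ---------------------------------------------------------------------------

def control_noise(raw: PerturbationDataset, min_values: int = 3) -> pd.Series:
    """Per-readout robust spread (1.4826 x MAD) of control fold changes.

    Control fold changes are pooled across donors and post-baseline
    timepoints; fewer than ``min_values`` per readout is an error because the
    spread cannot be estimated.
    """
    cfc = control_fold_change(raw)
    sizes = cfc.groupby("readout")["fc"].size()
    too_few = sizes[sizes < min_values]
    if not too_few.empty:
        raise ValueError(
            f"fewer than {min_values} control values for readouts: "
            f"{sorted(too_few.index)}")
    mad = cfc.groupby("readout")["fc"].apply(
        lambda x: float(np.median(np.abs(x - np.median(x)))))
    return MAD_SCALE * mad


def significance_filter(collapsed: pd.DataFrame, noise: pd.Series,
                        params: NormalizationParams) -> pd.DataFrame:
    """Classify each triple as phosphorylated / dephosphorylated / neither.

    Robust z = fc / spread; two-sided normal p; Benjamini-Hochberg within each
    donor at ``fdr_q`` (or a plain ``|z| >= z_crit`` cut when ``fdr_q`` is
    None).  A zero spread with nonzero fold change is flagged significant
    with a warning (degenerate noise estimate).
    """
    out = collapsed.copy()
    spread = out["readout"].map(noise)
    if spread.isna().any():
        missing = sorted(out.loc[spread.isna(), "readout"].unique())
        raise ValueError(f"no noise estimate for readouts: {missing}")
    zero_spread = spread == 0
    if zero_spread.any() and (out.loc[zero_spread, "fc"] != 0).any():
        warnings.warn("zero control spread for some readouts; nonzero fold "
                      "changes there are flagged significant", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_spread,
                     np.where(out["fc"] == 0, 0.0,
                              np.sign(out["fc"]) * np.inf),
                     out["fc"] / spread)
    out["z"] = z
    out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    if params.fdr_q is None:
        out["q"] = out["p"]
        significant = np.abs(out["z"]) >= params.z_crit
    else:
        out["q"] = np.nan
        for donor, idx in out.groupby("donor").groups.items():
            p = out.loc[idx, "p"].to_numpy()
            out.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
        significant = out["q"] < params.fdr_q
    out["state"] = NON_SIGNIFICANT
    out.loc[significant & (out["fc"] > 0), "state"] = PHOSPHORYLATED
    out.loc[significant & (out["fc"] < 0), "state"] = DEPHOSPHORYLATED
    return out


# ---------------------------------------------------------------------------
# Stage 3: Hill normalization
# ---------------------------------------------------------------------------

def hill(x: np.ndarray, ec50: float, k: float) -> np.ndarray:
    x = np.abs(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = x ** k / (ec50 ** k + x ** k)
    return np.where(x == 0, 0.0, v)


def hill_normalize(stated: pd.DataFrame,
                   params: NormalizationParams) -> NormalizedDataset:
    out = stated.copy()
    out["value"] = np.nan
    ec50_by_donor: dict[str, float] = {}
    for donor, sub in out.groupby("donor"):
        if params.ec50 is not None:
            ec50 = params.ec50
        else:
            pos = sub.loc[sub["state"] == PHOSPHORYLATED, "fc"].abs()
            if pos.empty:
                pos = sub.loc[sub["state"] != NON_SIGNIFICANT, "fc"].abs()
            ec50 = 0.5 * float(pos.median()) if not pos.empty else 1.0
            if ec50 <= 0:
                ec50 = 1.0
        ec50_by_donor[donor] = ec50
        mask = (out["donor"] == donor) & (out["state"] == PHOSPHORYLATED)
        out.loc[mask, "value"] = hill(out.loc[mask, "fc"].to_numpy(),
                                      ec50, params.hill_k)
    out.loc[out["state"] == DEPHOSPHORYLATED, "value"] = 0.0
    return NormalizedDataset(table=out, params=params,
                             meta={"ec50_by_donor": ec50_by_donor,
                                   "filter_scope": "per_donor"})


def normalize_dataset(raw: PerturbationDataset,
                      params: NormalizationParams | None = None
                      ) -> NormalizedDataset:
    """Full pipeline: fold change -> collapse -> filter -> Hill transform."""
    params = params or NormalizationParams()
    fc = fold_change(raw)
    collapsed = collapse_timepoints(fc)
    noise = control_noise(raw)
    stated = significance_filter(collapsed, noise, params)
    return hill_normalize(stated, params)
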