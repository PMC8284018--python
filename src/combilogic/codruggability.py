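"""Co-druggability scoring of network interactions.

For each interaction, with S the mean signaling activity of the interaction
in a subgroup network, the co-druggability score is

    |S_healthy - S_MS| - |S_healthy - S_treatment|

A non-positive score means the primary drug left the interaction at least as
far from healthy-like activity as the untreated disease did — either the
disease deregulated it and the drug failed to revert it, or the drug itself
pushed it away (off-target effect).  Selection applies the published filter
cascade: near-zero scores are collapsed to zero (lower-quartile threshold on
|score|), candidates need a collapsed score <= 0, a healthy-vs-treated
activity difference in the upper quartile that is also statistically
significant across donors (rank-sum p < alpha), and the interaction must be
active in the treated subgroup network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subgroup import SubgroupNetwork, rank_sum_p


@dataclass
class CoDruggabilityThresholds:
    collapse_quantile: float = 0.25
    difference_quantile: float = 0.75
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for q in (self.collapse_quantile, self.difference_quantile, self.alpha):
            if not 0 < q < 1:
                raise ValueError("quantiles and alpha must lie in (0, 1)")


def score(s_healthy: float, s_ms: float, s_treatment: float) -> float:
    """|S_healthy - S_MS| - |S_healthy - S_treatment|; inputs in [0, 1]."""
    for name, v in (("s_healthy", s_healthy), ("s_ms", s_ms),
                    ("s_treatment", s_treatment)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return abs(s_healthy - s_ms) - abs(s_healthy - s_treatment)


def score_table(healthy: SubgroupNetwork, ms: SubgroupNetwork,
                treated: SubgroupNetwork) -> pd.DataFrame:
    """One record per hyperedge: activities, score, healthy-treated difference."""
    if not (healthy.hyperedge_ids == ms.hyperedge_ids ==
            treated.hyperedge_ids):
        raise ValueError("subgroup networks disagree on the hyperedge list")
    sh, sm, st = (healthy.edge_activity, ms.edge_activity,
                  treated.edge_activity)
    return pd.DataFrame({
        "interaction": healthy.hyperedge_ids,
        "s_healthy": sh,
        "s_ms": sm,
        "s_treatment": st,
        "score": np.abs(sh - sm) - np.abs(sh - st),
        "difference_h_t": np.abs(sh - st),
    })


def select_codruggable(records: pd.DataFrame,
                       donor_weights_healthy: np.ndarray,
                       donor_weights_treated: np.ndarray,
                       thresholds: CoDruggabilityThresholds,
                       active: np.ndarray) -> pd.DataFrame:
    """Apply the collapse / difference / significance / activity filters.

    ``donor_weights_*`` are (n_donors, n_hyperedges) per-donor edge-weight
    matrices for the healthy and treated groups; the per-edge significance of
    the healthy-vs-treated difference is a two-sample Wilcoxon rank-sum test
    on them.  ``active`` is the treated subgroup's active-edge mask.
    Quantile thresholds are computed within this one treatment comparison.
    """
    wh = np.atleast_2d(np.asarray(donor_weights_healthy, dtype=float))
    wt = np.atleast_2d(np.asarray(donor_weights_treated, dtype=float))
    if wh.shape[0] < 2 or wt.shape[0] < 2:
        raise ValueError("need >= 2 donors per group for the rank-sum test")
    n_edges = len(records)
    if wh.shape[1] != n_edges or wt.shape[1] != n_edges:
        raise ValueError("donor weight matrices do not match the record list")

    out = records.copy()
    abs_scores = out["score"].abs().to_numpy()
    collapse_thr = float(np.quantile(abs_scores, thresholds.collapse_quantile))
    out["collapsed_score"] = np.where(abs_scores < collapse_thr, 0.0,
                                      out["score"])
    diff_thr = float(np.quantile(out["difference_h_t"].to_numpy(),
                                 thresholds.difference_quantile))
    pvals = np.ones(n_edges)
    for j in range(n_edges):
        a, b = wh[:, j], wt[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue  # identical constant weights: no difference, p = 1
        pvals[j] = rank_sum_p(a, b)
    out["p_value"] = pvals
    candidate = out["collapsed_score"] <= 0
    out["co_druggable"] = (candidate
                           & (out["difference_h_t"] >= diff_thr)
                           & (out["p_value"] < thresholds.alpha)
                           & np.asarray(active, dtype=bool))
    out.attrs["collapse_threshold"] = collapse_thr
    out.attrs["difference_threshold"] = diff_thr
    out.attrs["significance_test"] = "two-sample Wilcoxon rank-sum"
    return out


def codruggability_table(healthy: SubgroupNetwork, ms: SubgroupNetwork,
                         treated: SubgroupNetwork,
                         donor_weights_healthy: np.ndarray,
                         donor_weights_treated: np.ndarray,
                         thresholds: CoDruggabilityThresholds | None = None
                         ) -> pd.DataFrame:
    """Score + selection in one step for a single treatment comparison."""
    thresholds = thresholds or CoDruggabilityThresholds()
    records = score_table(healthy, ms, treated)
    flagged = select_codruggable(records, donor_weights_healthy,
                                 donor_weights_treated, thresholds,
                                 treated.active_mask)
    flagged.insert(0, "treatment", treated.group)
    return flagged
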