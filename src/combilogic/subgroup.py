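"""Subgroup networks: merging donor models, similarity, differential edges.

Donor models (per-hyperedge weights in [0, 1]) are merged within a donor
group by the per-edge arithmetic mean, giving a single *subgroup network*
whose strongest signals — edge activities in the upper quartile of the
group's nonzero activities — form the active-edge mask used by all
downstream topology analyses.  Network similarity between donors and
subgroup networks is the Jaccard distance on edge sets binarized at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .logic_fit import DonorModel

DEFAULT_BINARIZE_AT = 0.5
ACTIVE_QUANTILE = 0.75


@dataclass
class SubgroupNetwork:
    group: str
    edge_activity: np.ndarray
    active_mask: np.ndarray
    n_donors: int
    hyperedge_ids: list[str] = field(default_factory=list)

    def active_ids(self) -> set[str]:
        return {i for i, a in zip(self.hyperedge_ids, self.active_mask) if a}


def merge_subgroup(models: list[DonorModel], group: str,
                   hyperedge_ids: list[str] | None = None) -> SubgroupNetwork:
    """Per-edge arithmetic mean of donor edge weights."""
    if not models:
        raise ValueError(f"group {group!r} has no donors")
    lengths = {len(m.edge_weights) for m in models}
    if len(lengths) != 1:
        raise ValueError("donor models disagree on the hyperedge list")
    activity = np.mean([m.edge_weights for m in models], axis=0)
    net = SubgroupNetwork(group=group, edge_activity=activity,
                          active_mask=np.zeros(len(activity), dtype=bool),
                          n_donors=len(models),
                          hyperedge_ids=list(hyperedge_ids or
                                             map(str, range(len(activity)))))
    net.active_mask = active_edges(net)
    return net


def active_edges(net: SubgroupNetwork,
                 quantile: float = ACTIVE_QUANTILE) -> np.ndarray:
    """Mask of the strongest signals: activity >= the upper quartile of the
    group's nonzero activities (linear-interpolation percentile; ties at the
    threshold are active)."""
    nonzero = net.edge_activity[net.edge_activity > 0]
    if nonzero.size == 0:
        warnings.warn(f"subgroup {net.group!r} has no nonzero edge activity",
                      stacklevel=2)
        return np.zeros_like(net.edge_activity, dtype=bool)
    threshold = np.quantile(nonzero, quantile)
    return net.edge_activity >= threshold


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Wilcoxon rank-sum p (two-sided), as used throughout.

    The exact null distribution is used for small tie-free samples (the
    classical convention); with ties or large samples the continuity-
    corrected normal approximation applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 50) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def jaccard_distance(a: np.ndarray, b: np.ndarray,
                     binarize_at: float = DEFAULT_BINARIZE_AT) -> float:
    """1 - |A ∩ B| / |A ∪ B| on edge sets binarized at ``binarize_at``.

    Both sets empty -> distance 0 (identical empty networks).
    """
    a = np.asarray(a, dtype=float) >= binarize_at
    b = np.asarray(b, dtype=float) >= binarize_at
    if a.shape != b.shape:
        raise ValueError("edge-weight vectors differ in length")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return 1.0 - int(np.sum(a & b)) / union


@dataclass
class DistanceReport:
    per_donor: pd.DataFrame      # donor, group, distance (to reference network)
    group_medians: pd.Series
    background: np.ndarray       # all unordered donor-pair distances
    rank_sum_p: pd.Series        # per group vs background

    def __post_init__(self) -> None:
        d = self.per_donor["distance"]
        if ((d < 0) | (d > 1)).any():
            raise ValueError("distances must lie in [0, 1]")


def distance_report(donor_models: dict[str, dict[str, DonorModel]],
                    reference_group: str,
                    binarize_at: float = DEFAULT_BINARIZE_AT,
                    hyperedge_ids: list[str] | None = None) -> DistanceReport:
    """Distances of every donor to a reference subgroup mean network.

    Background similarity = Jaccard distances over all unordered donor pairs
    in the whole cohort; each group's donor-to-reference distances are
    compared to the background with a two-sample Wilcoxon rank-sum test.
    """
    if reference_group not in donor_models:
        raise ValueError(f"unknown reference group {reference_group!r}")
    for g, models in donor_models.items():
        if len(models) < 2:
            raise ValueError(f"group {g!r} needs >= 2 donors")
    ref_net = merge_subgroup(list(donor_models[reference_group].values()),
                             reference_group, hyperedge_ids)
    rows = []
    all_weights, labels = [], []
    for g, models in donor_models.items():
        for donor, m in sorted(models.items()):
            rows.append({"donor": donor, "group": g,
                         "distance": jaccard_distance(
                             m.edge_weights, ref_net.edge_activity,
                             binarize_at)})
            all_weights.append(m.edge_weights)
            labels.append(g)
    per_donor = pd.DataFrame(rows)
    n = len(all_weights)
    background = np.array([
        jaccard_distance(all_weights[i], all_weights[j], binarize_at)
        for i in range(n) for j in range(i + 1, n)])
    medians = per_donor.groupby("group")["distance"].median()
    pvals = {}
    for g in donor_models:
        d = per_donor.loc[per_donor["group"] == g, "distance"]
        pvals[g] = rank_sum_p(d.to_numpy(), background)
    return DistanceReport(per_donor=per_donor, group_medians=medians,
                          background=background, rank_sum_p=pd.Series(pvals))


def differential_interactions(a: SubgroupNetwork,
                              b: SubgroupNetwork) -> dict[str, set[str]]:
    """Partition hyperedges by the two active masks.

    Returns ``{"a_only", "b_only", "shared", "inactive"}`` — exhaustive and
    mutually exclusive over the common hyperedge list.
    """
    if a.hyperedge_ids != b.hyperedge_ids:
        raise ValueError("subgroup networks disagree on the hyperedge list")
    ids = np.array(a.hyperedge_ids)
    ma, mb = a.active_mask, b.active_mask
    return {
        "a_only": set(ids[ma & ~mb]),
        "b_only": set(ids[~ma & mb]),
        "shared": set(ids[ma & mb]),
        "inactive": set(ids[~ma & ~mb]),
    }


def weights_frame(donor_models: dict[str, dict[str, DonorModel]],
                  hyperedge_ids: list[str]) -> pd.DataFrame:
    """Donor x hyperedge weight matrix (heatmap-style), with a group column."""
    rows = {}
    groups = {}
    for g, models in donor_models.items():
        for donor, m in models.items():
            rows[donor] = m.edge_weights
            groups[donor] = g
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=hyperedge_ids).sort_index()
    frame.insert(0, "group", frame.index.map(groups))
    return frame
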