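"""Three-stage statistical confirmation of subgroup models.

Checks that the fitted subgroup networks are reflected in the underlying
phospho-measurements:

1. *Responding pairs* — per (group, stimulus, readout), a two-sided
   one-sample Wilcoxon signed-rank test of whether the collapsed fold
   changes (before Hill normalization) of the group's donors deviate from 0,
   Benjamini-Hochberg corrected within each group.
2. *Model support* — per (stimulus, readout), whether the readout is
   reachable from the stimulus over the subgroup network's active edges.
3. *Enrichment* — per group, a one-sided Fisher exact test of whether the
   significant pairs of stage 1 are enriched among the model-supported pairs
   of stage 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .combo_predict import active_graph
from .logic_fit import LogicModel
from .subgroup import SubgroupNetwork

MIN_DONORS = 5  # signed-rank validity floor


@dataclass
class ConfirmationTable:
    pairs: pd.DataFrame       # group, stimulus, readout, p, q, significant,
                              # model_supported
    enrichment: pd.DataFrame  # group, fisher_p + the 2x2 counts


def responding_pairs(collapsed: pd.DataFrame, groups: dict[str, str],
                     min_donors: int = MIN_DONORS,
                     alpha: float = 0.05,
                     adjusted_cutoff: bool = True) -> pd.DataFrame:
    """Stage 1: signed-rank p / BH q per (group, stimulus, readout).

    ``collapsed`` is the collapsed fold-change frame (donor, stimulus,
    readout, fc); ``groups`` maps donor -> group label.  Pairs where every
    fold change is exactly zero get p = 1 by convention (the signed-rank
    statistic is undefined) with a warning.  ``significant`` applies
    ``alpha`` to the BH-adjusted q by default (the stringent reading);
    set ``adjusted_cutoff=False`` to threshold raw p instead.
    """
    df = collapsed.copy()
    df["group"] = df["donor"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "donor"].unique())
        raise ValueError(f"donors without group label: {missing}")
    rows = []
    warned = False
    for (group, stim, readout), sub in df.groupby(
            ["group", "stimulus", "readout"], sort=True):
        fc = sub["fc"].to_numpy()
        if len(fc) < min_donors:
            raise ValueError(
                f"group {group!r} has {len(fc)} donors for ({stim}, {readout});"
                f" signed-rank needs >= {min_donors}")
        if np.all(fc == 0):
            if not warned:
                warnings.warn("all-zero fold changes for some pairs; "
                              "p = 1 by convention", stacklevel=2)
                warned = True
            p = 1.0
        else:
            p = float(stats.wilcoxon(fc, alternative="two-sided",
                                     zero_method="wilcox").pvalue)
        rows.append({"group": group, "stimulus": stim, "readout": readout,
                     "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for g, idx in out.groupby("group").groups.items():
        out.loc[idx, "q"] = multipletests(out.loc[idx, "p"].to_numpy(),
                                          method="fdr_bh")[1]
    out["significant"] = (out["q"] if adjusted_cutoff else out["p"]) < alpha
    return out


def model_support(model: LogicModel, group_net: SubgroupNetwork,
                  stimuli: list[str], readouts: list[str]) -> pd.DataFrame:
    """Stage 2: readout reachable from stimulus over the group's active edges."""
    g = active_graph(model, group_net)
    rows = []
    for s in stimuli:
        lengths = (nx.single_source_shortest_path_length(g, s)
                   if s in g else {})
        for m in readouts:
            rows.append({"group": group_net.group, "stimulus": s,
                         "readout": m, "model_supported": m in lengths})
    return pd.DataFrame(rows)


def enrichment(significant: np.ndarray, supported: np.ndarray
               ) -> tuple[float, np.ndarray]:
    """Stage 3: one-sided Fisher exact p on significant x supported.

    Table layout: rows = supported / not supported, columns = significant /
    not significant; the alternative is 'greater' (significant pairs enriched
    among supported).  A degenerate margin (all or none supported, or all or
    none significant) yields p = 1 with a warning.
    """
    significant = np.asarray(significant, dtype=bool)
    supported = np.asarray(supported, dtype=bool)
    if significant.shape != supported.shape or significant.size == 0:
        raise ValueError("need matching non-empty significance/support vectors")
    table = np.array([
        [int(np.sum(supported & significant)),
         int(np.sum(supported & ~significant))],
        [int(np.sum(~supported & significant)),
         int(np.sum(~supported & ~significant))],
    ])
    if 0 in table.sum(axis=1) or 0 in table.sum(axis=0):
        warnings.warn("degenerate margin in enrichment table; p = 1",
                      stacklevel=2)
        return 1.0, table
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return p, table


def confirm_subgroups(collapsed: pd.DataFrame, groups: dict[str, str],
                      model: LogicModel,
                      subgroup_nets: dict[str, SubgroupNetwork],
                      stimuli: list[str], readouts: list[str],
                      alpha: float = 0.05,
                      min_donors: int = MIN_DONORS) -> ConfirmationTable:
    """Run the full three-stage confirmation for every subgroup."""
    stage1 = responding_pairs(collapsed, groups, min_donors=min_donors,
                              alpha=alpha)
    supports = [model_support(model, net, stimuli, readouts)
                for net in subgroup_nets.values()]
    stage2 = pd.concat(supports, ignore_index=True)
    pairs = stage1.merge(stage2, on=["group", "stimulus", "readout"],
                         how="inner")
    rows = []
    for g, sub in pairs.groupby("group"):
        p, table = enrichment(sub["significant"].to_numpy(),
                              sub["model_supported"].to_numpy())
        rows.append({"group": g, "fisher_p": p,
                     "supported_significant": table[0, 0],
                     "supported_nonsignificant": table[0, 1],
                     "unsupported_significant": table[1, 0],
                     "unsupported_nonsignificant": table[1, 1]})
    return ConfirmationTable(pairs=pairs, enrichment=pd.DataFrame(rows))
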