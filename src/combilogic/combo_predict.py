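"""Topology-based combination-therapy prediction.

Given the co-druggable interactions of a treatment's subgroup network, a
graph search over the network's *active* edges finds, for every co-druggable
interaction u -> v, each experimental stimulus s with a directed path
s ⇝ u and each measurable readout m with a directed path v ⇝ m.  Such a
(stimulus, interaction, readout) triple is a testable combination: the
stimulus engages the deregulated interaction and the readout reports the
effect.  Path search is sign-agnostic; the desired modulation direction is
carried separately (inhibit when the treated activity overshoots healthy,
activate when it undershoots).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .logic_fit import LogicModel
from .pkn import AndGate
from .subgroup import SubgroupNetwork

PREDICTION_COLUMNS = ["treatment", "interaction", "stimulus", "readout",
                      "direction", "path_length_up", "path_length_down"]


@dataclass(frozen=True)
class CombinationPrediction:
    treatment: str
    interaction: str
    stimulus: str
    readout: str
    direction: str  # 'inhibit' | 'activate'
    path_length_up: int
    path_length_down: int


def _edge_endpoints(model: LogicModel, edge_index: int) -> tuple[list[str], str]:
    h = model.hyperedges[edge_index]
    if isinstance(h, AndGate):
        return [n for n, _ in h.inputs], h.target
    return [h.source], h.target


def active_graph(model: LogicModel, net: SubgroupNetwork) -> nx.DiGraph:
    """Directed graph of the subgroup's active hyperedges (gates expanded)."""
    g = nx.DiGraph()
    g.add_nodes_from(model.node_names)
    for j, act in enumerate(net.active_mask):
        if not act:
            continue
        sources, target = _edge_endpoints(model, j)
        for s in sources:
            g.add_edge(s, target)
    return g


def predict_combinations(model: LogicModel, treated_net: SubgroupNetwork,
                         flagged: pd.DataFrame, stimuli: list[str],
                         readouts: list[str]) -> pd.DataFrame:
    """Enumerate (stimulus, co-druggable interaction, readout) predictions.

    ``flagged`` is a co-druggability record table; only rows with
    ``co_druggable`` True are mapped.  The co-druggable edge itself is part
    of the searchable active graph.  Shortest path lengths (in edges) from
    stimulus to the interaction source and from the interaction target to
    the readout are recorded.
    """
    g = active_graph(model, treated_net)
    id_to_index = {e: j for j, e in enumerate(model.hyperedge_ids)}
    rows: list[CombinationPrediction] = []
    for rec in flagged.itertuples(index=False):
        if not rec.co_druggable:
            continue
        j = id_to_index.get(rec.interaction)
        if j is None:
            raise ValueError(f"unknown interaction {rec.interaction!r}")
        sources, target = _edge_endpoints(model, j)
        direction = "inhibit" if rec.s_treatment > rec.s_healthy else "activate"
        up: dict[str, int] = {}
        for s in stimuli:
            if s not in g:
                continue
            lengths = nx.single_source_shortest_path_length(g, s)
            best = min((lengths[u] for u in sources if u in lengths),
                       default=None)
            if best is not None:
                up[s] = best
        if not up:
            continue  # no upstream stimulus reaches this interaction
        down = nx.single_source_shortest_path_length(g, target)
        for s, lu in sorted(up.items()):
            for m in readouts:
                if m in down:
                    rows.append(CombinationPrediction(
                        treatment=rec.treatment, interaction=rec.interaction,
                        stimulus=s, readout=m, direction=direction,
                        path_length_up=lu, path_length_down=down[m]))
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=PREDICTION_COLUMNS)


def summarize_by_interaction(flagged_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per interaction, in how many treatments it was co-druggable.

    Input: one co-druggability record table per treatment.  Interactions
    flagged nowhere are absent; output sorted by descending treatment count.
    """
    counts: dict[str, set[str]] = {}
    for table in flagged_tables:
        hits = table[table["co_druggable"]]
        for rec in hits.itertuples(index=False):
            counts.setdefault(rec.interaction, set()).add(rec.treatment)
    rows = [{"interaction": e, "n_treatments": len(t)}
            for e, t in counts.items()]
    return (pd.DataFrame(rows, columns=["interaction", "n_treatments"])
            .sort_values(["n_treatments", "interaction"],
                         ascending=[False, True])
            .reset_index(drop=True))
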