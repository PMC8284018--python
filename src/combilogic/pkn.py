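"""Prior knowledge signaling networks.

A prior knowledge network (PKN) is a literature-derived hypothesis space for
logic-model fitting: a signed directed graph of (de)phosphorylation events,
optionally extended with AND-gate hyperedges encoding protein-complex
requirements.  Nodes carry a role — ``stimulus`` (ligand applied in vitro),
``drug`` (perturbing compound, modeled as a stimulus or an inhibitor clamp),
``readout`` (measured phosphoprotein) or ``intermediate`` — and an optional
pathway label used for reporting.

Interchange formats: SIF (``source<TAB>relation<TAB>target`` with relation
``1``/``-1``) for the plain interactions, a node-annotation CSV
(name, role, pathway) and an AND-gate sidecar CSV (gate_id, input, sign,
target), because SIF cannot express hyperedges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("stimulus", "drug", "intermediate", "readout")


class SifParseError(ValueError):
    """Raised on a malformed SIF line; carries the 1-based line number."""


@dataclass(frozen=True)
class Node:
    name: str
    role: str = "intermediate"
    pathway: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for node {self.name!r}")


@dataclass(frozen=True)
class Interaction:
    """A signed directed edge; sign +1 activates, -1 inhibits."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class AndGate:
    """Hyperedge: the target requires the conjunction of all signed inputs.

    ``inputs`` is stored sorted so that two gates with the same input set
    compare equal regardless of construction order.
    """

    inputs: tuple[tuple[str, int], ...]
    target: str

    def __post_init__(self) -> None:
        if len(self.inputs) < 2:
            raise ValueError("an AND gate needs at least 2 inputs")
        object.__setattr__(self, "inputs", tuple(sorted(self.inputs)))
        for _, sign in self.inputs:
            if sign not in (1, -1):
                raise ValueError("AND-gate input signs must be +1 or -1")


@dataclass
class PriorKnowledgeNetwork:
    nodes: dict[str, Node] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)
    and_gates: list[AndGate] = field(default_factory=list)
    #: readouts found unreachable from every stimulus during preprocessing
    flagged_readouts: set[str] = field(default_factory=set)

    # -- construction -----------------------------------------------------
    def add_node(self, name: str, role: str = "intermediate",
                 pathway: str | None = None) -> None:
        if name in self.nodes:
            existing = self.nodes[name]
            # explicit roles win over the auto-declared intermediate default
            if role != "intermediate" or pathway is not None:
                self.nodes[name] = Node(name, role,
                                        pathway if pathway is not None
                                        else existing.pathway)
        else:
            self.nodes[name] = Node(name, role, pathway)

    def add_interaction(self, source: str, target: str, sign: int,
                        allow_self_loop: bool = False) -> None:
        if source == target and not allow_self_loop:
            raise ValueError(f"self-loop {source!r} -> {target!r} not allowed")
        inter = Interaction(source, target, sign)
        if inter in self.interactions:
            logger.warning("duplicate interaction %s %+d %s ignored",
                           source, sign, target)
            return
        self.add_node(source)
        self.add_node(target)
        self.interactions.append(inter)

    def add_and_gate(self, inputs: Sequence[tuple[str, int]], target: str) -> None:
        gate = AndGate(tuple(inputs), target)
        for name, _ in gate.inputs:
            if name not in self.nodes:
                raise ValueError(f"AND-gate input {name!r} not in network")
        if gate.target not in self.nodes:
            raise ValueError(f"AND-gate target {target!r} not in network")
        if gate not in self.and_gates:
            self.and_gates.append(gate)

    # -- views ------------------------------------------------------------
    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, node in self.nodes.items() if node.role == role}

    @property
    def stimuli(self) -> set[str]:
        return self.nodes_with_role("stimulus")

    @property
    def drugs(self) -> set[str]:
        return self.nodes_with_role("drug")

    @property
    def readouts(self) -> set[str]:
        return self.nodes_with_role("readout")

    def to_digraph(self, include_gates: bool = True) -> nx.MultiDiGraph:
        """Directed multigraph view; AND gates contribute input->target arcs."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for it in self.interactions:
            g.add_edge(it.source, it.target, sign=it.sign)
        if include_gates:
            for gate in self.and_gates:
                for name, sign in gate.inputs:
                    g.add_edge(name, gate.target, sign=sign, gate=True)
        return g

    def copy(self) -> "PriorKnowledgeNetwork":
        return PriorKnowledgeNetwork(
            nodes=dict(self.nodes),
            interactions=list(self.interactions),
            and_gates=list(self.and_gates),
            flagged_readouts=set(self.flagged_readouts),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PriorKnowledgeNetwork({len(self.nodes)} nodes, "
                f"{len(self.interactions)} interactions, "
                f"{len(self.and_gates)} AND gates)")


# ---------------------------------------------------------------------------
# SIF + sidecar I/O
# ---------------------------------------------------------------------------

def read_sif(path) -> PriorKnowledgeNetwork:
    """Read a tab-separated SIF file (relation column ``1`` or ``-1``).

    All referenced nodes are auto-declared intermediates; roles can be
    overridden afterwards with :func:`read_annotations`.  Duplicate identical
    lines are de-duplicated with a logged warning; the same (source, target)
    pair with both signs is kept as two parallel edges.
    """
    pkn = PriorKnowledgeNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SifParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}: {line!r}")
            source, relation, target = (p.strip() for p in parts)
            if relation not in ("1", "-1"):
                raise SifParseError(
                    f"{path}:{lineno}: unknown relation token {relation!r} "
                    "(expected '1' or '-1')")
            pkn.add_interaction(source, target, int(relation))
    return pkn


def write_sif(pkn: PriorKnowledgeNetwork, path) -> None:
    with open(path, "w") as fh:
        for it in pkn.interactions:
            fh.write(f"{it.source}\t{it.sign}\t{it.target}\n")


def read_annotations(pkn: PriorKnowledgeNetwork, path) -> None:
    """Apply a node-annotation CSV (columns: name, role[, pathway]) in place."""
    table = pd.read_csv(path)
    for _, row in table.iterrows():
        pathway = row.get("pathway")
        if pathway is None or pd.isna(pathway):
            pathway = None
        pkn.nodes[row["name"]] = Node(row["name"], row["role"], pathway)


def write_annotations(pkn: PriorKnowledgeNetwork, path) -> None:
    rows = [{"name": n.name, "role": n.role, "pathway": n.pathway}
            for n in pkn.nodes.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_and_gates(pkn: PriorKnowledgeNetwork, path) -> None:
    """Load the AND-gate sidecar CSV (gate_id, input, sign, target) in place."""
    table = pd.read_csv(path)
    for gate_id, group in table.groupby("gate_id", sort=True):
        targets = group["target"].unique()
        if len(targets) != 1:
            raise ValueError(f"gate {gate_id}: inconsistent targets {targets}")
        inputs = [(r.input, int(r.sign)) for r in group.itertuples(index=False)]
        pkn.add_and_gate(inputs, targets[0])


def write_and_gates(pkn: PriorKnowledgeNetwork, path) -> None:
    rows = []
    for i, gate in enumerate(pkn.and_gates):
        for name, sign in gate.inputs:
            rows.append({"gate_id": i, "input": name, "sign": sign,
                         "target": gate.target})
    pd.DataFrame(rows, columns=["gate_id", "input", "sign", "target"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Reachability
# ---------------------------------------------------------------------------

def reachable(edges: Iterable, from_node: str, to_node: str) -> bool:
    """True iff a directed path from ``from_node`` to ``to_node`` exists.

    ``edges`` may be ``(source, target)`` pairs or :class:`Interaction`
    objects; signs are ignored, reachability is purely topological.
    """
    g = nx.DiGraph()
    g.add_node(from_node)
    g.add_node(to_node)
    for e in edges:
        if isinstance(e, Interaction):
            g.add_edge(e.source, e.target)
        else:
            g.add_edge(e[0], e[1])
    return nx.has_path(g, from_node, to_node)


# ---------------------------------------------------------------------------
# Identifiability preprocessing
# ---------------------------------------------------------------------------

def _descendants_from(g: nx.DiGraph, sources: set[str]) -> set[str]:
    out: set[str] = set()
    for s in sources:
        if s in g:
            out.add(s)
            out |= nx.descendants(g, s)
    return out


def preprocess_identifiability(
        pkn: PriorKnowledgeNetwork,
        stimuli: set[str],
        readouts: set[str]) -> PriorKnowledgeNetwork:
    """Reduce a PKN to the part constrainable by the measurement panel.

    Iterates to a fixed point: (a) remove undesignated nodes with no directed
    path from any stimulus (non-controllable), (b) remove undesignated nodes
    with no directed path to any readout (non-observable), (c) compress
    unmeasured, unperturbed pass-through nodes (in-degree = out-degree = 1 and
    not part of any AND gate), rewiring source -> target with the product of
    the two signs.  Designated nodes (stimuli, drugs, readouts) are never
    removed; a readout unreachable from every stimulus is retained, flagged in
    ``flagged_readouts`` and reported with a warning.
    """
    missing = (set(stimuli) | set(readouts)) - set(pkn.nodes)
    if missing:
        raise ValueError(f"designated nodes not in network: {sorted(missing)}")

    net = pkn.copy()
    for name in stimuli:
        net.nodes[name] = replace(net.nodes[name], role="stimulus")
    for name in readouts:
        net.nodes[name] = replace(net.nodes[name], role="readout")

    def designated(name: str) -> bool:
        return net.nodes[name].role != "intermediate"

    changed = True
    while changed:
        changed = False
        g = net.to_digraph(include_gates=True)
        simple = nx.DiGraph(g)

        controllable = _descendants_from(simple, set(stimuli) & set(net.nodes))
        observable = _descendants_from(simple.reverse(copy=False),
                                       set(readouts) & set(net.nodes))
        drop = {n for n in net.nodes
                if not designated(n)
                and (n not in controllable or n not in observable)}
        if drop:
            changed = True
            net.interactions = [it for it in net.interactions
                                if it.source not in drop and it.target not in drop]
            net.and_gates = [gt for gt in net.and_gates
                             if gt.target not in drop
                             and all(i not in drop for i, _ in gt.inputs)]
            for n in drop:
                del net.nodes[n]
            continue

        gate_members = {gt.target for gt in net.and_gates}
        gate_members |= {i for gt in net.and_gates for i, _ in gt.inputs}
        in_edges: dict[str, list[Interaction]] = {}
        out_edges: dict[str, list[Interaction]] = {}
        for it in net.interactions:
            in_edges.setdefault(it.target, []).append(it)
            out_edges.setdefault(it.source, []).append(it)
        for n in list(net.nodes):
            if designated(n) or n in gate_members:
                continue
            ins = in_edges.get(n, [])
            outs = out_edges.get(n, [])
            if len(ins) == 1 and len(outs) == 1:
                up, down = ins[0], outs[0]
                if up.source == n or down.target == n:
                    continue  # self-loop, leave alone
                net.interactions.remove(up)
                net.interactions.remove(down)
                del net.nodes[n]
                if up.source != down.target:
                    merged = Interaction(up.source, down.target,
                                         up.sign * down.sign)
                    if merged not in net.interactions:
                        net.interactions.append(merged)
                changed = True
                break  # degree maps stale; recompute

    for r in set(readouts) & set(net.nodes):
        g = net.to_digraph()
        if not any(s in g and nx.has_path(g, s, r)
                   for s in set(stimuli) & set(net.nodes)):
            net.flagged_readouts.add(r)
            warnings.warn(f"readout {r!r} unreachable from every stimulus; "
                          "retained but flagged", stacklevel=2)
    return net


# ---------------------------------------------------------------------------
# Closeness centrality
# ---------------------------------------------------------------------------

def closeness_centrality(
        pkn: PriorKnowledgeNetwork,
        pathway_labels: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Harmonic out-closeness per node, ranked within pathway.

    Harmonic formulation on outgoing distances, ``C(v) = (1/(n-1)) *
    sum_{u != v} 1/d(v, u)``, so disconnected graphs are well defined
    (unreachable pairs contribute 0; an isolated node scores 0).
    """
    if not pkn.nodes:
        raise ValueError("network is empty")
    g = nx.DiGraph(pkn.to_digraph())
    n = g.number_of_nodes()
    # networkx harmonic_centrality sums 1/d(u, v) over incoming paths;
    # reverse to score outgoing information spread.
    raw = nx.harmonic_centrality(g.reverse(copy=False))
    scale = 1.0 / (n - 1) if n > 1 else 0.0
    rows = []
    for name in pkn.nodes:
        pathway = None
        if pathway_labels is not None:
            pathway = pathway_labels.get(name)
        if pathway is None:
            pathway = pkn.nodes[name].pathway
        rows.append({"node": name, "pathway": pathway,
                     "closeness": raw.get(name, 0.0) * scale})
    table = pd.DataFrame(rows)
    table["rank_in_pathway"] = (
        table.groupby(table["pathway"].fillna(""))["closeness"]
        .rank(ascending=False, method="min").astype(int))
    return table.sort_values(["pathway", "rank_in_pathway", "node"],
                             na_position="last").reset_index(drop=True)
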