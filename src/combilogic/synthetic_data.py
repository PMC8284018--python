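"""Synthetic perturbation-phosphoproteomics cohorts with known ground truth.

The generator emulates the structure of a multi-center ex vivo stimulation
study: a donor cohort partitioned into a healthy group, an untreated disease
group and several single-drug treatment groups; a panel of single-stimulus
conditions plus a media control; and per (donor, condition, readout,
timepoint) mean-fluorescence-intensity (MFI) values.

Ground truth is Boolean: a healthy sub-model of the PKN (a selection over its
candidate hyperedges), from which every non-healthy group differs in a fixed
number of *deregulated* edges.  Treatment groups revert part of the disease's
deregulated set back to healthy — the unreverted remainder is what the
downstream co-druggability analysis should rediscover.  Measurements are the
simulated Boolean readout states mapped to MFI (state 1 = baseline x
effect_size) under multiplicative log-normal noise; MFI is strictly positive,
so multiplicative noise on the log scale is the natural error model.

Inhibition in generated ground truths is realized inside AND gates
(activator AND NOT inhibitor): under OR-of-hyperedges semantics a bare
inhibitory edge fires whenever its source is at rest, which would activate
the unstimulated control and leave the edge unconstrained by
stimulus-vs-control fold changes.  Bare inhibitory edges remain supported by
the logic engine; the generator simply defaults to the identifiable motif.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logic_fit import LogicModel
from .midas import CONTROL_NAME, LONG_COLUMNS, PerturbationDataset
from .pkn import PriorKnowledgeNetwork, reachable

#: the study's measurement panel: 17 phosphoprotein readouts
DEFAULT_READOUTS = (
    "AKT1", "CREB1", "FAK1", "GSK3A", "HSPB1", "IKBA", "JUN", "MK03", "MK12",
    "MP2K1", "PTN11", "STAT1", "STAT3", "STAT5A", "STAT6", "TF65", "WNK1",
)

#: 20 stimulation conditions (ligands, drugs, stressors); media control is extra
DEFAULT_STIMULI = (
    "AntiCD3", "ConA", "IFNG", "IL1A", "IL6", "LPS", "NaCl", "PolyIC", "TNFA",
    "S1P", "VitD3", "BDNF", "EGCG", "INS", "BN201", "DMF", "FTY",
    "Teriflunomide", "IFNB1A", "H2O2",
)

DEFAULT_GROUPS = ("healthy", "untreated", "IFNB", "GA", "NTZ", "FTY", "EGCG")


@dataclass
class CohortSpec:
    n_donors_per_group: int = 26
    groups: tuple[str, ...] = DEFAULT_GROUPS
    stimuli: tuple[str, ...] = DEFAULT_STIMULI
    readouts: tuple[str, ...] = DEFAULT_READOUTS
    timepoints: tuple[float, ...] = (0.0, 5.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors_per_group < 1:
            raise ValueError("need at least one donor per group")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must start at 0 (baseline)")


@dataclass
class NoiseModel:
    baseline_mfi: float = 500.0
    effect_size: float = 4.0
    cv: float = 0.15
    donor_variability: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_mfi <= 0:
            raise ValueError("baseline MFI must be positive")
        if self.effect_size <= 1:
            raise ValueError("effect size must exceed 1")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if not 0 <= self.donor_variability < 0.5:
            raise ValueError("donor flip probability must be in [0, 0.5)")


@dataclass
class GroundTruth:
    base_network: PriorKnowledgeNetwork
    model: LogicModel
    group_edge_states: dict[str, np.ndarray]
    deregulated_edges: dict[str, set[str]]
    slow_edges: set[int] = field(default_factory=set)

    def states_frame(self) -> pd.DataFrame:
        return pd.DataFrame({g: s.astype(int)
                             for g, s in self.group_edge_states.items()},
                            index=self.model.hyperedge_ids)


# ---------------------------------------------------------------------------
# Random PKN
# ---------------------------------------------------------------------------

def random_pkn(stimuli=DEFAULT_STIMULI, readouts=DEFAULT_READOUTS,
               n_intermediates: int = 12, seed: int = 0,
               and_gate_frac: float = 0.2,
               extra_edge_frac: float = 0.25) -> PriorKnowledgeNetwork:
    """Layered random signaling network: stimuli -> intermediates -> readouts.

    All single-input edges are activating; a fraction of targets additionally
    receives an AND gate pairing an activator with a NOT-inhibitor, which is
    how inhibition enters generated ground truths (see module docstring).
    """
    rng = np.random.default_rng(seed)
    pkn = PriorKnowledgeNetwork()
    for s in stimuli:
        pkn.add_node(s, role="stimulus")
    inters = [f"I{i:02d}" for i in range(n_intermediates)]
    for m in inters:
        pkn.add_node(m, role="intermediate")
    for r in readouts:
        pkn.add_node(r, role="readout")

    # each intermediate is driven by one earlier node (stimulus or intermediate)
    for i, m in enumerate(inters):
        pool = list(stimuli) + inters[:i]
        src = pool[rng.integers(len(pool))]
        pkn.add_interaction(src, m, 1)
    # spread stimuli: every stimulus feeds at least one intermediate
    for s in stimuli:
        if not any(it.source == s for it in pkn.interactions):
            m = inters[rng.integers(len(inters))]
            if not any(it.source == s and it.target == m
                       for it in pkn.interactions):
                pkn.add_interaction(s, m, 1)
    # each readout is driven by 1-2 intermediates; a second driver must not
    # share stimulus ancestry with the first, else the two routes would be
    # equal-cost alternative explanations of the same response
    import networkx as nx

    def stim_ancestors(node: str) -> frozenset:
        g = nx.DiGraph([(it.source, it.target) for it in pkn.interactions])
        if node not in g:
            return frozenset()
        anc = nx.ancestors(g, node) | {node}
        return frozenset(a for a in anc if a in set(stimuli))

    for r in readouts:
        k = 1 + int(rng.random() < 0.4)
        first = str(inters[rng.integers(len(inters))])
        pkn.add_interaction(first, r, 1)
        if k == 2:
            seen = stim_ancestors(first)
            others = [m for m in inters
                      if m != first and not (stim_ancestors(m) & seen)]
            if others:
                pkn.add_interaction(str(others[rng.integers(len(others))]),
                                    r, 1)
    # extra forward wiring for crosstalk
    n_extra = int(extra_edge_frac * (n_intermediates + len(readouts)))
    order = list(stimuli) + inters + list(readouts)
    pos = {n: i for i, n in enumerate(order)}
    for _ in range(n_extra):
        a, b = rng.choice(order, size=2, replace=False)
        if pos[a] > pos[b]:
            a, b = b, a
        if a == b or b in stimuli:
            continue
        if not any(it.source == a and it.target == b for it in pkn.interactions):
            pkn.add_interaction(str(a), str(b), 1)
    # AND gates: activator AND NOT inhibitor on a subset of wired targets
    targets = sorted({it.target for it in pkn.interactions})
    n_gates = int(and_gate_frac * len(targets))
    for t in rng.choice(targets, size=min(n_gates, len(targets)), replace=False):
        t = str(t)
        activators = [it.source for it in pkn.interactions if it.target == t]
        upstream = [n for n in order if pos[n] < pos[t] and n != t
                    and n not in activators]
        if not activators or not upstream:
            continue
        act = activators[rng.integers(len(activators))]
        inh = str(upstream[rng.integers(len(upstream))])
        try:
            pkn.add_and_gate([(act, 1), (inh, -1)], t)
        except ValueError:
            continue
        # the complex replaces plain activation; keeping both would leave an
        # observationally equivalent single-edge twin of the gate
        pkn.interactions = [it for it in pkn.interactions
                            if not (it.source == act and it.target == t
                                    and it.sign == 1)]
    return pkn


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def condition_panel(spec: CohortSpec) -> list[frozenset]:
    """Control condition first, then one single-stimulus condition each."""
    return [frozenset()] + [frozenset([s]) for s in spec.stimuli]


def _observable(model: LogicModel, state: np.ndarray,
                conditions: list[frozenset], readouts: list[str]) -> np.ndarray:
    mat = model.readout_matrix(state, conditions, readouts)
    return np.nan_to_num(mat, nan=-1.0)


def identifiable_edges(model: LogicModel, state: np.ndarray,
                       conditions: list[frozenset],
                       readouts: list[str]) -> np.ndarray:
    """Boolean mask: flipping the hyperedge changes some simulated readout."""
    base = _observable(model, state, conditions, readouts)
    mask = np.zeros(model.n_hyperedges, dtype=bool)
    for j in range(model.n_hyperedges):
        flipped = state.copy()
        flipped[j] = ~flipped[j]
        mask[j] = not np.array_equal(
            _observable(model, flipped, conditions, readouts), base)
    return mask


def ground_truth_identifiable(truth: "GroundTruth", group: str,
                              spec: CohortSpec) -> np.ndarray:
    """Mask of the group's selected, output-relevant hyperedges.

    This is the recovery target for fitting: selected edges whose individual
    removal changes the simulated readout matrix under the condition panel.
    """
    stimuli = [s for s in spec.stimuli if s in truth.base_network.nodes]
    readouts = [r for r in spec.readouts if r in truth.base_network.nodes]
    conditions = [frozenset()] + [frozenset([s]) for s in stimuli]
    state = truth.group_edge_states[group]
    return identifiable_edges(truth.model, state, conditions, readouts) & state


def make_ground_truth(pkn: PriorKnowledgeNetwork, spec: CohortSpec,
                      n_deregulated: int, seed: int,
                      select_prob: float = 0.75,
                      n_unreverted: int | None = None) -> GroundTruth:
    """Sample subgroup Boolean networks with a known deregulation structure.

    The healthy state is a random sub-model of the PKN, minimized so that
    every selected edge is output-relevant and no smaller single-edge
    substitution reproduces the same readouts (a locally minimal,
    identifiable sub-model), under which at least half the readouts respond
    to some stimulus.  The untreated group flips ``n_deregulated``
    output-changing candidate edges, gain-of-function (off in healthy,
    constitutive over-activation in disease) preferred.  Each treatment
    group keeps ``n_unreverted`` of the disease's gain flips (default: half,
    rounded up) — the unreverted deregulation the downstream co-druggability
    analysis should find — and differs from healthy in fresh off-target
    flips up to the same total, so every non-healthy group differs from
    healthy in exactly ``n_deregulated`` edges.
    """
    model = LogicModel(pkn)
    stimuli = [s for s in spec.stimuli if s in pkn.nodes]
    readouts = [r for r in spec.readouts if r in pkn.nodes]
    if not any(reachable(pkn.interactions, s, r)
               for s in stimuli for r in readouts):
        raise ValueError("PKN has no stimulus -> readout path")
    if n_deregulated > model.n_hyperedges:
        raise ValueError("cannot deregulate more edges than exist")

    conditions = condition_panel(
        CohortSpec(**{**spec.__dict__, "stimuli": tuple(stimuli)}))
    rng = np.random.default_rng([seed % (2 ** 31), 11])

    def observable(state: np.ndarray) -> np.ndarray:
        return _observable(model, state, conditions, readouts)

    def flip_candidates(state: np.ndarray,
                        exclude: set[int]) -> tuple[list[int], list[int]]:
        """Output-changing flips: (gains: off -> on, losses: on -> off)."""
        gains, losses = [], []
        base = observable(state)
        for j in range(model.n_hyperedges):
            if j in exclude:
                continue
            flipped = state.copy()
            flipped[j] = ~flipped[j]
            if not np.array_equal(observable(flipped), base):
                (losses if state[j] else gains).append(j)
        return gains, losses

    def prune_to_core(state: np.ndarray) -> np.ndarray:
        """Drop selected hyperedges that do not affect the observable readout
        matrix, AND gates before single edges, until every remaining selected
        edge is output-relevant."""
        state = state.copy()
        n_plain = len(model.pkn.interactions)
        order = [j for j in range(model.n_hyperedges) if j >= n_plain] + \
                [j for j in range(n_plain)]
        changed = True
        while changed:
            changed = False
            base = observable(state)
            for j in order:
                if not state[j]:
                    continue
                state[j] = False
                if np.array_equal(observable(state), base):
                    changed = True
                    break
                state[j] = True
        return state

    def minimize_model(state: np.ndarray) -> np.ndarray:
        """Locally minimal sub-model with unchanged readouts: prune redundant
        edges, then greedily adopt output-neutral single-edge additions that
        let strictly more edges be pruned (e.g., a direct edge replacing a
        two-edge chain), so a size-penalized fit has nothing cheaper to
        substitute."""
        state = prune_to_core(state)
        improved = True
        while improved:
            improved = False
            base = observable(state)
            for j in range(model.n_hyperedges):
                if state[j]:
                    continue
                cand = state.copy()
                cand[j] = True
                if not np.array_equal(observable(cand), base):
                    continue
                pruned = prune_to_core(cand)
                if pruned.sum() < state.sum():
                    state = pruned
                    improved = True
                    break
        return state

    def introduces_redundancy(state: np.ndarray) -> bool:
        return prune_to_core(state).sum() < state.sum()

    def sample_flip_sequence(base_state: np.ndarray, n: int,
                             exclude: set[int],
                             forced: list[int]) -> list[int]:
        """Apply ``forced`` flips then sample ``n - len(forced)`` more, each
        output-changing in the context of the flips already applied, gains
        preferred, avoiding flips that make other selected edges redundant."""
        state = base_state.copy()
        chosen: list[int] = []
        for j in forced:
            state[j] = ~state[j]
            chosen.append(j)
        while len(chosen) < n:
            gains, losses = flip_candidates(state, exclude | set(chosen))
            picked = None
            for pool in (gains, losses):
                if picked is not None:
                    break
                for j in rng.permutation(pool).tolist() if pool else []:
                    cand = state.copy()
                    cand[j] = ~cand[j]
                    if not introduces_redundancy(cand):
                        picked = j
                        break
            if picked is None:  # fall back to any output-changing flip
                pool = gains + losses
                if not pool:
                    raise ValueError(
                        "ran out of identifiable deregulation candidates")
                picked = int(rng.choice(pool))
            state[picked] = ~state[picked]
            chosen.append(picked)
        return chosen

    healthy = None
    for _ in range(100):
        cand = minimize_model(rng.random(model.n_hyperedges) < select_prob)
        obs = observable(cand)
        responding = (obs[1:] > 0).any(axis=0).sum()
        gains, losses = flip_candidates(cand, set())
        if (responding >= max(1, len(readouts) // 2)
                and len(gains) + len(losses) >= 2 * n_deregulated
                and len(gains) >= n_deregulated):
            healthy = cand
            break
    if healthy is None:
        raise ValueError("could not sample a responsive healthy sub-model "
                         "with enough deregulation candidates")

    states: dict[str, np.ndarray] = {}
    dereg: dict[str, set[str]] = {}
    ids = model.hyperedge_ids
    groups = list(spec.groups)
    if "healthy" not in groups:
        raise ValueError("cohort must contain a 'healthy' group")
    states["healthy"] = healthy

    disease_flips: list[int] = []
    if n_deregulated > 0:
        disease_flips = sample_flip_sequence(healthy, n_deregulated,
                                             set(), [])
        # gains first, so the kept (unreverted) subset is active in disease
        disease_flips.sort(key=lambda j: bool(healthy[j]))
    if n_unreverted is None:
        n_unreverted = (n_deregulated + 1) // 2

    for g in groups:
        if g == "healthy":
            continue
        if g == "untreated":
            flips = disease_flips
        else:
            keep = disease_flips[:n_unreverted]
            flips = sample_flip_sequence(healthy, n_deregulated,
                                         set(disease_flips) - set(keep),
                                         keep)
        st = healthy.copy()
        for j in flips:
            st[j] = ~st[j]
        states[g] = st
        dereg[g] = {ids[j] for j in flips}
    return GroundTruth(base_network=pkn, model=model,
                       group_edge_states=states, deregulated_edges=dereg)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(truth: GroundTruth, spec: CohortSpec,
                    noise: NoiseModel) -> PerturbationDataset:
    """Boolean-simulate every donor and emit a MIDAS-shaped MFI dataset.

    Per donor: its group's edge state (with per-edge flips at probability
    ``donor_variability``) is simulated under the control and each
    single-stimulus condition; readout state 1 maps to ``baseline_mfi x
    effect_size`` and 0 to ``baseline_mfi`` at the post-stimulation
    timepoints (slow edges act only at the last one); the baseline timepoint
    is always at baseline level; every value is multiplied by log-normal
    noise.  Deterministic given ``spec.seed``.
    """
    model = truth.model
    stimuli = [s for s in spec.stimuli if s in truth.base_network.nodes]
    readouts = [r for r in spec.readouts if r in truth.base_network.nodes]
    conditions = [frozenset()] + [frozenset([s]) for s in stimuli]
    cond_names = [CONTROL_NAME] + stimuli
    sigma = float(np.sqrt(np.log1p(noise.cv ** 2)))
    t_late = spec.timepoints[-1]

    records = []
    donor_idx = 0
    for group in spec.groups:
        g_state = truth.group_edge_states[group]
        for d in range(spec.n_donors_per_group):
            donor = f"{group}_{d:03d}"
            rng = np.random.default_rng(
                [spec.seed % (2 ** 31), 101, donor_idx])
            donor_idx += 1
            state = g_state.copy()
            if noise.donor_variability > 0:
                flips = rng.random(model.n_hyperedges) < noise.donor_variability
                state = state ^ flips
            full = np.nan_to_num(
                model.readout_matrix(state, conditions, readouts), nan=0.0)
            if truth.slow_edges:
                early_sel = state.copy()
                early_sel[sorted(truth.slow_edges)] = False
                early = np.nan_to_num(
                    model.readout_matrix(early_sel, conditions, readouts),
                    nan=0.0)
            else:
                early = full
            for c, cname in enumerate(cond_names):
                for t in spec.timepoints:
                    if t == 0:
                        level = np.full(len(readouts), noise.baseline_mfi)
                    else:
                        st = full[c] if t == t_late else early[c]
                        level = noise.baseline_mfi * noise.effect_size ** st
                    if noise.cv > 0:
                        level = level * np.exp(
                            sigma * rng.standard_normal(len(readouts)))
                    for r, val in zip(readouts, level):
                        records.append((donor, group, cname, r, t, float(val)))
    data = pd.DataFrame.from_records(records, columns=LONG_COLUMNS)
    return PerturbationDataset(data=data, meta={
        "seed": spec.seed, "noise": noise.__dict__.copy(),
        "groups": list(spec.groups)})


def write_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar with per-group edge states and deregulated edge sets."""
    payload = {
        "hyperedges": truth.model.hyperedge_ids,
        "group_edge_states": {g: s.astype(int).tolist()
                              for g, s in truth.group_edge_states.items()},
        "deregulated_edges": {g: sorted(e)
                              for g, e in truth.deregulated_edges.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
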