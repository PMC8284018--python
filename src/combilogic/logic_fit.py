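"""Boolean logic model simulation and genetic-algorithm training.

A logic model is a selection (bit vector) over the candidate hyperedges of a
preprocessed PKN: every signed single-input interaction plus every AND gate.
OR semantics apply across the selected hyperedges sharing a target; within a
hyperedge a sign of +1 contributes the input value and −1 its negation, and
an AND gate contributes the conjunction of its signed inputs.

Simulation is the synchronous fixpoint: starting from the applied stimuli
(value 1, everything else 0), all nodes update simultaneously until the state
stops changing or ``2 × n_nodes`` steps elapse; entries still changing after
that (oscillations from negative feedback) are *unresolved* and penalized in
the objective rather than compared to data.

Training minimizes

    MSE(simulated readouts, normalized data over defined pairs)
    + na_penalty × fraction(unresolved among defined pairs)
    + size_factor × selected / total hyperedges

with a seeded bit-vector genetic algorithm (tournament selection, uniform
crossover, single-bit mutation, elitism, stall-based early stop).  The donor
model is the per-hyperedge median of the selections whose score lies within a
relative tolerance of the best across independent runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .pkn import AndGate, PriorKnowledgeNetwork

UNRESOLVED = "unresolved"


@dataclass
class TrainingParams:
    size_factor: float = 1e-4
    na_penalty: float = 1.0
    n_runs: int = 10
    rel_tol: float = 0.1
    population: int = 50
    max_generations: int = 500
    stall_generations: int = 100
    mutation_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 <= self.rel_tol < 1:
            raise ValueError("rel_tol must be in [0, 1)")
        if self.size_factor < 0 or self.na_penalty < 0:
            raise ValueError("penalties must be nonnegative")


@dataclass
class DonorModel:
    """Tolerance-ensemble consensus: per-hyperedge selection-bit median."""

    edge_weights: np.ndarray
    best_score: float
    ensemble_size: int

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble must contain at least one solution")
        w = np.asarray(self.edge_weights, dtype=float)
        if w.min() < 0 or w.max() > 1:
            raise ValueError("edge weights must lie in [0, 1]")
        self.edge_weights = w


class LogicModel:
    """Candidate hyperedge space of a preprocessed PKN, compiled for speed."""

    def __init__(self, pkn: PriorKnowledgeNetwork):
        self.pkn = pkn
        self.node_names: list[str] = sorted(pkn.nodes)
        self.node_index = {n: i for i, n in enumerate(self.node_names)}
        self.hyperedges: list = list(pkn.interactions) + list(pkn.and_gates)
        self.hyperedge_ids: list[str] = [self._edge_id(h) for h in self.hyperedges]
        self._inputs: list[np.ndarray] = []
        self._signs: list[np.ndarray] = []
        self._targets = np.empty(len(self.hyperedges), dtype=int)
        for j, h in enumerate(self.hyperedges):
            if isinstance(h, AndGate):
                idx = [(self.node_index[n], s) for n, s in h.inputs]
                tgt = h.target
            else:
                idx = [(self.node_index[h.source], h.sign)]
                tgt = h.target
            self._inputs.append(np.array([i for i, _ in idx], dtype=int))
            self._signs.append(np.array([s for _, s in idx], dtype=int))
            self._targets[j] = self.node_index[tgt]
        self.clamped_roles = {"stimulus", "drug"}

    @staticmethod
    def _edge_id(h) -> str:
        if isinstance(h, AndGate):
            terms = "+".join(("!" if s < 0 else "") + n for n, s in h.inputs)
            return f"{terms}={h.target}"
        return f"{'!' if h.sign < 0 else ''}{h.source}={h.target}"

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    # -- simulation -------------------------------------------------------
    def simulate_conditions(self, selection: np.ndarray,
                            conditions: list[frozenset],
                            inhibited: frozenset = frozenset()) -> np.ndarray:
        """Synchronous fixpoint over several conditions at once.

        Returns a (n_conditions, n_nodes) float array with entries in
        {0.0, 1.0} or NaN for unresolved (oscillating) nodes.
        """
        n = len(self.node_names)
        n_c = len(conditions)
        stim_mask = np.zeros((n_c, n), dtype=bool)
        for c, on in enumerate(conditions):
            for name in on:
                stim_mask[c, self.node_index[name]] = True
        inhib_idx = [self.node_index[i] for i in inhibited]
        active = [j for j in range(self.n_hyperedges) if selection[j]]

        def step(state: np.ndarray) -> np.ndarray:
            new = np.zeros_like(state)
            for j in active:
                val = np.ones(n_c, dtype=bool)
                for i, s in zip(self._inputs[j], self._signs[j]):
                    val &= state[:, i] if s > 0 else ~state[:, i]
                new[:, self._targets[j]] |= val
            new |= stim_mask
            if inhib_idx:
                new[:, inhib_idx] = False
            return new

        state = stim_mask.copy()
        max_steps = 2 * n
        converged = False
        for _ in range(max_steps):
            new = step(state)
            if np.array_equal(new, state):
                converged = True
                break
            state = new
        out = state.astype(float)
        if not converged:
            varying = np.zeros_like(state)
            probe = state
            for _ in range(max(n, 2)):
                nxt = step(probe)
                varying |= nxt != probe
                probe = nxt
                if np.array_equal(nxt, state):
                    break
            out[varying] = np.nan
        return out

    def readout_matrix(self, selection: np.ndarray,
                       conditions: list[frozenset],
                       readouts: list[str],
                       inhibited: frozenset = frozenset()) -> np.ndarray:
        states = self.simulate_conditions(selection, conditions, inhibited)
        cols = [self.node_index[r] for r in readouts]
        return states[:, cols]


def simulate(model: LogicModel, stimuli_on: set[str],
             inhibited: set[str] = frozenset(),
             selection: np.ndarray | None = None) -> dict:
    """Single-condition synchronous fixpoint; per-node 0, 1 or 'unresolved'."""
    clampable = {n for n in model.pkn.nodes
                 if model.pkn.nodes[n].role in model.clamped_roles}
    bad = set(stimuli_on) - clampable
    if bad:
        raise ValueError(f"not stimulus/drug nodes: {sorted(bad)}")
    if selection is None:
        selection = np.ones(model.n_hyperedges, dtype=bool)
    states = model.simulate_conditions(selection, [frozenset(stimuli_on)],
                                       frozenset(inhibited))[0]
    return {name: (UNRESOLVED if np.isnan(v) else int(v))
            for name, v in zip(model.node_names, states)}


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

@dataclass
class DonorData:
    """Normalized values for one donor, aligned to a condition panel."""

    conditions: list[frozenset]
    readouts: list[str]
    values: np.ndarray  # (n_conditions, n_readouts), NaN = excluded

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.conditions), len(self.readouts)):
            raise ValueError("values shape does not match panel")
        if not np.any(np.isfinite(self.values)):
            raise ValueError("donor has zero defined data points")


def score_simulation(sim: np.ndarray, values: np.ndarray,
                     n_selected: int, n_total: int,
                     size_factor: float, na_penalty: float) -> float:
    defined = np.isfinite(values)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("zero defined data points")
    unresolved = defined & np.isnan(sim)
    compared = defined & ~unresolved
    mse = 0.0
    if compared.any():
        mse = float(np.mean((sim[compared] - values[compared]) ** 2))
    na_frac = unresolved.sum() / n_def
    size = n_selected / n_total if n_total else 0.0
    return mse + na_penalty * float(na_frac) + size_factor * size


class Evaluator:
    """Scores genomes against one donor, memoizing simulations.

    ``sim_cache`` maps genome bytes to the simulated readout matrix, which
    depends only on the genome and condition panel — it can (and should) be
    shared across donors and GA runs of the same cohort.
    """

    def __init__(self, model: LogicModel, data: DonorData,
                 params: TrainingParams, sim_cache: dict | None = None):
        self.model = model
        self.data = data
        self.params = params
        self.sim_cache = sim_cache if sim_cache is not None else {}
        self._score_cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, genome: np.ndarray) -> float:
        key = np.packbits(genome).tobytes()
        score = self._score_cache.get(key)
        if score is not None:
            return score
        sim = self.sim_cache.get(key)
        if sim is None:
            sim = self.model.readout_matrix(genome, self.data.conditions,
                                            self.data.readouts)
            self.sim_cache[key] = sim
        score = score_simulation(sim, self.data.values, int(genome.sum()),
                                 self.model.n_hyperedges,
                                 self.params.size_factor,
                                 self.params.na_penalty)
        self._score_cache[key] = score
        self.n_evaluations += 1
        return score


def objective(model: LogicModel, selection: np.ndarray, data: DonorData,
              size_factor: float = 1e-4, na_penalty: float = 1.0) -> float:
    """Score one selection against one donor's normalized data."""
    sim = model.readout_matrix(np.asarray(selection, dtype=bool),
                               data.conditions, data.readouts)
    return score_simulation(sim, data.values, int(np.sum(selection)),
                            model.n_hyperedges, size_factor, na_penalty)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _ga_run(evaluate: Evaluator, n_bits: int, params: TrainingParams,
            rng: np.random.Generator) -> tuple[np.ndarray, float]:
    pop = rng.random((params.population, n_bits)) < 0.5
    scores = np.array([evaluate(g) for g in pop])
    best_i = int(np.argmin(scores))
    best, best_score = pop[best_i].copy(), float(scores[best_i])
    stall = 0
    for _ in range(params.max_generations):
        # tournament selection (size 3) for each parent slot
        idx = rng.integers(0, params.population, size=(2 * params.population, 3))
        winners = idx[np.arange(idx.shape[0]), np.argmin(scores[idx], axis=1)]
        new_pop = np.empty_like(pop)
        new_pop[0] = best  # elitism
        for k in range(1, params.population):
            pa, pb = pop[winners[2 * k]], pop[winners[2 * k + 1]]
            mask = rng.random(n_bits) < 0.5
            child = np.where(mask, pa, pb)
            if rng.random() < params.mutation_rate:
                child[rng.integers(n_bits)] ^= True
            new_pop[k] = child
        pop = new_pop
        scores = np.array([evaluate(g) for g in pop])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score - 1e-15:
            best, best_score = pop[gen_best].copy(), float(scores[gen_best])
            stall = 0
        else:
            stall += 1
            if stall >= params.stall_generations:
                break
    return best, best_score


def ga_optimize(model: LogicModel, data: DonorData, params: TrainingParams,
                sim_cache: dict | None = None
                ) -> list[tuple[np.ndarray, float]]:
    """Independent seeded GA runs; returns the best (selection, score) per run."""
    evaluate = Evaluator(model, data, params, sim_cache)
    runs = []
    for r in range(params.n_runs):
        rng = np.random.default_rng([params.seed % (2 ** 31), r])
        runs.append(_ga_run(evaluate, model.n_hyperedges, params, rng))
    return runs


def exhaustive_search(model: LogicModel, data: DonorData,
                      params: TrainingParams) -> tuple[np.ndarray, float]:
    """Global optimum by enumerating all 2^H selections (small H only)."""
    h = model.n_hyperedges
    if h > 20:
        raise ValueError("exhaustive search limited to <= 20 hyperedges")
    evaluate = Evaluator(model, data, params)
    best, best_score = None, np.inf
    for bits in itertools.product((False, True), repeat=h):
        genome = np.array(bits, dtype=bool)
        s = evaluate(genome)
        if s < best_score:
            best, best_score = genome, s
    return best, float(best_score)


def consensus_model(runs: list[tuple[np.ndarray, float]],
                    rel_tol: float) -> DonorModel:
    """Median selection over all runs within relative tolerance of the best.

    The tolerance band is ``score <= best * (1 + rel_tol)`` including its
    border; the per-hyperedge median of an even-sized ensemble is the mean of
    the two central values, so weights of exactly 0.5 can occur.
    """
    if not runs:
        raise ValueError("no optimization runs provided")
    best_score = min(s for _, s in runs)
    cutoff = best_score * (1 + rel_tol) + 1e-12
    ensemble = np.array([sel for sel, s in runs if s <= cutoff], dtype=float)
    weights = np.median(ensemble, axis=0)
    return DonorModel(edge_weights=weights, best_score=float(best_score),
                      ensemble_size=ensemble.shape[0])


def fit_donor(model: LogicModel, data: DonorData, params: TrainingParams,
              sim_cache: dict | None = None
              ) -> tuple[DonorModel, list[tuple[np.ndarray, float]]]:
    runs = ga_optimize(model, data, params, sim_cache)
    return consensus_model(runs, params.rel_tol), runs


def fit_cohort(model: LogicModel, donor_data: dict[str, DonorData],
               params: TrainingParams) -> dict[str, DonorModel]:
    """Fit every donor, sharing one simulation cache, seeded per donor."""
    sim_cache: dict = {}
    out: dict[str, DonorModel] = {}
    for i, (donor, data) in enumerate(sorted(donor_data.items())):
        donor_params = TrainingParams(**{**params.__dict__,
                                         "seed": (params.seed + 7919 * (i + 1))
                                                 % (2 ** 31)})
        out[donor], _ = fit_donor(model, data, donor_params, sim_cache)
    return out
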