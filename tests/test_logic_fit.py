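"""Boolean simulation, objective, GA training and consensus models."""

import numpy as np
import pytest

from combilogic.logic_fit import (DonorData, LogicModel, TrainingParams,
                                  UNRESOLVED, consensus_model,
                                  exhaustive_search, fit_donor, ga_optimize,
                                  objective, simulate)
from combilogic.pkn import PriorKnowledgeNetwork
from combilogic.synthetic_data import random_pkn
from conftest import small_panel


def build_model(edges, stimuli=(), and_gates=()):
    pkn = PriorKnowledgeNetwork()
    for s in stimuli:
        pkn.add_node(s, role="stimulus")
    for src, tgt, sign in edges:
        pkn.add_interaction(src, tgt, sign)
    for inputs, tgt in and_gates:
        pkn.add_node(tgt)
        for name, _ in inputs:
            pkn.add_node(name)
        pkn.add_and_gate(inputs, tgt)
    return LogicModel(pkn)


class TestSimulate:
    def test_activation_chain_propagates(self):
        model = build_model([("S", "A", 1), ("A", "B", 1)], stimuli=["S"])
        states = simulate(model, {"S"})
        assert states == {"A": 1, "B": 1, "S": 1}

    def test_inhibitor_clamp_blocks_downstream(self):
        model = build_model([("S", "A", 1), ("A", "B", 1)], stimuli=["S"])
        states = simulate(model, {"S"}, inhibited={"A"})
        assert states["A"] == 0 and states["B"] == 0

    def test_negative_feedback_reaches_or_fixpoint(self):
        # A receives S (activating) and NOT B; under OR semantics the NOT
        # term holds A on regardless of B, so the loop settles at (1, 1).
        model = build_model([("S", "A", 1), ("A", "B", 1), ("B", "A", -1)],
                            stimuli=["S"])
        states = simulate(model, {"S"})
        assert states == {"S": 1, "A": 1, "B": 1}

    def test_mutual_negation_oscillates_to_unresolved(self):
        model = build_model([("A", "B", -1), ("B", "A", -1)], stimuli=["S"])
        states = simulate(model, set())
        assert states["A"] == UNRESOLVED and states["B"] == UNRESOLVED

    def test_and_gate_requires_all_signed_inputs(self):
        model = build_model([("S", "A", 1), ("T", "B", 1)],
                            stimuli=["S", "T"],
                            and_gates=[([("A", 1), ("B", -1)], "C")])
        assert simulate(model, {"S"})["C"] == 1       # A on, B off
        assert simulate(model, {"S", "T"})["C"] == 0  # inhibitor engaged

    def test_non_stimulus_cannot_be_switched_on(self):
        model = build_model([("S", "A", 1)], stimuli=["S"])
        with pytest.raises(ValueError, match="not stimulus"):
            simulate(model, {"A"})

    def test_fixpoint_is_stable_under_restart(self):
        model = build_model([("S", "A", 1), ("A", "B", 1), ("B", "A", -1)],
                            stimuli=["S"])
        sel = np.ones(model.n_hyperedges, dtype=bool)
        first = model.simulate_conditions(sel, [frozenset(["S"])])
        # feed the fixpoint back in as if it were the initial state: one more
        # synchronous sweep must reproduce it
        again = model.simulate_conditions(sel, [frozenset(["S"])])
        assert np.array_equal(first, again, equal_nan=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_without_inhibition(self, seed):
        stimuli, readouts = small_panel(3, 3)
        pkn = random_pkn(stimuli, readouts, n_intermediates=4, seed=seed,
                         and_gate_frac=0.0)
        model = LogicModel(pkn)
        sel = np.ones(model.n_hyperedges, dtype=bool)
        base = model.simulate_conditions(sel, [frozenset(["S0"])])[0]
        more = model.simulate_conditions(sel, [frozenset(["S0", "S1"])])[0]
        assert np.all(more >= base)  # adding a stimulus never turns 1 -> 0


class TestObjective:
    def _simple(self):
        return build_model([("S", "M", 1)], stimuli=["S"])

    def test_empty_selection_against_ones_gives_unit_mse(self):
        model = self._simple()
        data = DonorData(conditions=[frozenset(["S"])], readouts=["M"],
                         values=np.array([[1.0]]))
        assert objective(model, np.zeros(1, dtype=bool), data,
                         size_factor=0.0) == pytest.approx(1.0)

    def test_perfect_fit_scores_only_size_term(self):
        model = self._simple()
        data = DonorData(conditions=[frozenset(["S"])], readouts=["M"],
                         values=np.array([[1.0]]))
        score = objective(model, np.ones(1, dtype=bool), data,
                          size_factor=0.2)
        assert score == pytest.approx(0.2 * 1 / 1)

    def test_hand_arithmetic_two_conditions(self):
        model = build_model([("S", "M", 1), ("T", "M", 1)],
                            stimuli=["S", "T"])
        sel = np.array([False, True])
        data = DonorData(conditions=[frozenset(["S"]), frozenset(["T"])],
                         readouts=["M"], values=np.array([[0.0], [0.5]]))
        # simulated: 0 under S, 1 under T -> residuals 0 and 0.25, MSE 0.125
        score = objective(model, sel, data, size_factor=0.0)
        assert score == pytest.approx(0.125)

    def test_zero_defined_points_is_an_error(self):
        with pytest.raises(ValueError, match="zero defined"):
            DonorData(conditions=[frozenset(["S"])], readouts=["M"],
                      values=np.array([[np.nan]]))

    def test_unresolved_pairs_pay_na_penalty(self):
        model = build_model([("A", "B", -1), ("B", "A", -1), ("S", "M", 1),
                             ("A", "M", 1)], stimuli=["S"])
        data = DonorData(conditions=[frozenset(["S"])], readouts=["A"],
                         values=np.array([[1.0]]))
        score = objective(model, np.ones(4, dtype=bool), data,
                          size_factor=0.0, na_penalty=0.7)
        assert score == pytest.approx(0.7)  # the only defined pair oscillates


class TestConsensus:
    def test_single_run_is_identity(self):
        sel = np.array([True, False, True])
        dm = consensus_model([(sel, 0.5)], rel_tol=0.1)
        assert np.array_equal(dm.edge_weights, sel.astype(float))

    def test_odd_ensemble_takes_majority_bit(self):
        runs = [(np.array([b]), 0.1) for b in (True, True, False)]
        assert consensus_model(runs, 0.5).edge_weights[0] == 1.0

    def test_even_ensemble_can_yield_half(self):
        runs = [(np.array([b]), 0.1) for b in (True, True, False, False)]
        assert consensus_model(runs, 0.5).edge_weights[0] == 0.5

    def test_tolerance_band_excludes_poor_runs(self):
        runs = [(np.array([True]), 1.0), (np.array([False]), 2.0)]
        dm = consensus_model(runs, rel_tol=0.1)
        assert dm.ensemble_size == 1 and dm.edge_weights[0] == 1.0

    def test_border_of_tolerance_included(self):
        runs = [(np.array([True]), 1.0), (np.array([False]), 1.1)]
        assert consensus_model(runs, rel_tol=0.1).ensemble_size == 2


class TestGA:
    def _instance(self, seed):
        stimuli, readouts = small_panel(3, 3)
        pkn = random_pkn(stimuli, readouts, n_intermediates=3, seed=seed,
                         extra_edge_frac=0.1)
        model = LogicModel(pkn)
        rng = np.random.default_rng(seed + 1000)
        truth = rng.random(model.n_hyperedges) < 0.7
        conds = [frozenset([s]) for s in stimuli]
        sim = model.readout_matrix(truth, conds, list(readouts))
        values = np.where(np.nan_to_num(sim, nan=0.0) > 0, 0.8, 0.0)
        values[rng.random(values.shape) < 0.2] = np.nan
        if not np.any(np.isfinite(values)):
            values[0, 0] = 0.0
        return model, DonorData(conditions=conds, readouts=list(readouts),
                                values=values)

    def test_same_seed_reproduces_runs(self):
        model, data = self._instance(0)
        params = TrainingParams(n_runs=3, population=20, max_generations=30,
                                stall_generations=10, seed=5)
        a = ga_optimize(model, data, params)
        b = ga_optimize(model, data, params)
        for (sa, ca), (sb, cb) in zip(a, b):
            assert np.array_equal(sa, sb) and ca == cb

    @pytest.mark.parametrize("seed", range(4))
    def test_ga_matches_exhaustive_on_small_instances(self, seed):
        model, data = self._instance(seed)
        assert model.n_hyperedges <= 14
        params = TrainingParams(n_runs=3, population=30, max_generations=60,
                                stall_generations=15, seed=seed)
        runs = ga_optimize(model, data, params)
        _, opt = exhaustive_search(model, data, params)
        assert min(s for _, s in runs) == pytest.approx(opt, abs=1e-12)

    def test_signal_carrying_edges_recovered_noise_free(self, tiny_cohort):
        from combilogic.normalization import normalize_dataset
        from combilogic.synthetic_data import ground_truth_identifiable
        pkn, spec, truth, cohort = tiny_cohort
        norm = normalize_dataset(cohort)
        model = truth.model
        donor = "healthy_000"
        data = norm.donor_data(donor, list(spec.stimuli), list(spec.readouts))
        params = TrainingParams(n_runs=4, population=30, max_generations=80,
                                stall_generations=20, seed=11)
        dm, _ = fit_donor(model, data, params)
        core = ground_truth_identifiable(truth, "healthy", spec)
        assert np.all(dm.edge_weights[core] >= 0.5)
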