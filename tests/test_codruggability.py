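"""Co-druggability score, the binary truth table, and the selection filters."""

import numpy as np
import pandas as pd
import pytest

from combilogic.codruggability import (CoDruggabilityThresholds, score,
                                       score_table, select_codruggable)
from combilogic.subgroup import SubgroupNetwork, merge_subgroup
from combilogic.logic_fit import DonorModel

# (healthy, MS, treated) -> score; rows flagged co-druggable under maximal
# healthy-vs-treated difference and forced significance
TRUTH_TABLE = {
    (0, 0, 0): (0, False),
    (0, 0, 1): (-1, True),
    (0, 1, 0): (1, False),
    (0, 1, 1): (0, True),
    (1, 0, 0): (0, True),
    (1, 0, 1): (1, False),
    (1, 1, 0): (-1, True),
    (1, 1, 1): (0, False),
}


def net_from_activity(activity, group="g"):
    m = DonorModel(edge_weights=np.asarray(activity, dtype=float),
                   best_score=0.0, ensemble_size=1)
    return merge_subgroup([m], group,
                          hyperedge_ids=[f"e{i}" for i in range(len(activity))])


class TestScore:
    @pytest.mark.parametrize("inputs,expected",
                             [(k, v[0]) for k, v in TRUTH_TABLE.items()])
    def test_binary_truth_table(self, inputs, expected):
        assert score(*inputs) == expected

    def test_fractional_arithmetic(self):
        assert score(0.8, 0.2, 0.9) == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="s_ms"):
            score(0.5, 1.2, 0.5)

    def test_treatment_equal_to_disease_scores_zero(self):
        for x in np.linspace(0, 1, 7):
            assert score(0.3, x, x) == 0

    def test_perfect_reversion_scores_distance(self):
        for s_h, s_ms in [(0.1, 0.9), (0.5, 0.5), (1.0, 0.0)]:
            assert score(s_h, s_ms, s_h) == pytest.approx(abs(s_h - s_ms))


class TestScoreTable:
    def test_identical_networks_score_zero(self):
        net = net_from_activity([0.2, 0.8, 1.0])
        table = score_table(net, net, net)
        assert (table["score"] == 0).all()

    def test_binary_rows_match_truth_table(self):
        rows = list(TRUTH_TABLE)
        h = net_from_activity([r[0] for r in rows])
        m = net_from_activity([r[1] for r in rows])
        t = net_from_activity([r[2] for r in rows])
        table = score_table(h, m, t)
        assert table["score"].tolist() == [TRUTH_TABLE[r][0] for r in rows]

    def test_random_networks_bounded(self):
        rng = np.random.default_rng(3)
        h, m, t = (net_from_activity(rng.random(30)) for _ in range(3))
        table = score_table(h, m, t)
        assert table["score"].between(-1, 1).all()

    def test_mismatched_edge_lists_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            score_table(net_from_activity([1]), net_from_activity([1, 0]),
                        net_from_activity([1]))


def binary_truth_table_selection():
    """Truth-table scenario with forced significance and maximal differences."""
    rows = list(TRUTH_TABLE)
    h = net_from_activity([r[0] for r in rows])
    m = net_from_activity([r[1] for r in rows])
    t = net_from_activity([r[2] for r in rows])
    records = score_table(h, m, t)
    # donor weights: constant at the group value, with a tiny jitter so the
    # rank-sum test sees the separation wherever the means differ
    rng = np.random.default_rng(0)
    wh = np.tile([r[0] for r in rows], (6, 1)) + rng.normal(0, 1e-3, (6, 8))
    wt = np.tile([r[2] for r in rows], (6, 1)) + rng.normal(0, 1e-3, (6, 8))
    flagged = select_codruggable(records, wh, wt,
                                 CoDruggabilityThresholds(),
                                 active=np.ones(8, dtype=bool))
    return rows, flagged


class TestSelection:
    def test_truth_table_rows_flagged_exactly(self):
        rows, flagged = binary_truth_table_selection()
        expected = [TRUTH_TABLE[r][1] for r in rows]
        assert flagged["co_druggable"].tolist() == expected

    def test_flagged_set_is_subset_of_active(self):
        rows = list(TRUTH_TABLE)
        h = net_from_activity([r[0] for r in rows])
        m = net_from_activity([r[1] for r in rows])
        t = net_from_activity([r[2] for r in rows])
        records = score_table(h, m, t)
        rng = np.random.default_rng(1)
        wh = np.tile([r[0] for r in rows], (5, 1)) + rng.normal(0, 1e-3, (5, 8))
        wt = np.tile([r[2] for r in rows], (5, 1)) + rng.normal(0, 1e-3, (5, 8))
        active = np.zeros(8, dtype=bool)
        active[1] = True
        flagged = select_codruggable(records, wh, wt,
                                     CoDruggabilityThresholds(), active)
        assert flagged.loc[flagged["co_druggable"], "interaction"].tolist() \
            == ["e1"]

    def test_removing_significance_filter_only_grows_the_set(self):
        rows, flagged = binary_truth_table_selection()
        relaxed = flagged.copy()
        relaxed["co_druggable_nosig"] = (
            (relaxed["collapsed_score"] <= 0)
            & (relaxed["difference_h_t"]
               >= flagged.attrs["difference_threshold"]))
        assert (relaxed["co_druggable_nosig"]
                | ~relaxed["co_druggable"]).all()

    def test_identical_scores_degenerate_collapse(self):
        records = pd.DataFrame({
            "interaction": ["e0", "e1"],
            "s_healthy": [0.5, 0.5], "s_ms": [0.5, 0.5],
            "s_treatment": [0.5, 0.5],
            "score": [0.0, 0.0], "difference_h_t": [0.0, 0.0]})
        flagged = select_codruggable(
            records, np.full((3, 2), 0.5), np.full((3, 2), 0.5),
            CoDruggabilityThresholds(), np.ones(2, dtype=bool))
        assert (flagged["collapsed_score"] == 0).all()
        assert not flagged["co_druggable"].any()  # nothing significant

    def test_full_reversion_cohort_has_no_codruggable_edges(self):
        # treatment reverts every deregulated edge: treated == healthy
        rng = np.random.default_rng(5)
        base = rng.random(12)
        h = net_from_activity(base)
        m = net_from_activity(np.clip(base + rng.choice([0, 0.8], 12), 0, 1))
        t = net_from_activity(base)
        records = score_table(h, m, t)
        wh = np.tile(base, (6, 1))
        wt = np.tile(base, (6, 1))
        flagged = select_codruggable(records, wh, wt,
                                     CoDruggabilityThresholds(),
                                     np.ones(12, dtype=bool))
        assert not flagged["co_druggable"].any()

    def test_needs_two_donors_per_group(self):
        records = pd.DataFrame({
            "interaction": ["e0"], "s_healthy": [0.0], "s_ms": [1.0],
            "s_treatment": [1.0], "score": [0.0], "difference_h_t": [1.0]})
        with pytest.raises(ValueError, match=">= 2 donors"):
            select_codruggable(records, np.zeros((1, 1)), np.ones((2, 1)),
                               CoDruggabilityThresholds(),
                               np.ones(1, dtype=bool))
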