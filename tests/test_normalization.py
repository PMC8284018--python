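"""Normalization: fold changes, timepoint collapse, 3-state filter, Hill map."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from combilogic.midas import LONG_COLUMNS, PerturbationDataset
from combilogic.normalization import (DEPHOSPHORYLATED, NON_SIGNIFICANT,
                                      PHOSPHORYLATED, NormalizationParams,
                                      collapse_timepoints, control_noise,
                                      fold_change, hill, hill_normalize,
                                      normalize_dataset, significance_filter)


def build_dataset(rows) -> PerturbationDataset:
    return PerturbationDataset(
        data=pd.DataFrame(rows, columns=LONG_COLUMNS))


def simple_rows(stim_values, control=100.0):
    """One donor, one readout; stim_values maps (stimulus, time) -> MFI."""
    rows = [("d0", "g", "media", "R", 0.0, control)]
    for t in (5.0, 25.0):
        rows.append(("d0", "g", "media", "R", t, control))
    for (stim, t), v in stim_values.items():
        rows.append(("d0", "g", stim, "R", 0.0, control))
        rows.append(("d0", "g", stim, "R", t, v))
    return rows


class TestFoldChange:
    def test_equal_to_control_gives_zero(self):
        ds = build_dataset(simple_rows({("s1", 5.0): 100.0,
                                        ("s1", 25.0): 100.0}))
        fc = fold_change(ds)
        assert fc["fc"].abs().max() == 0.0

    def test_doubling_gives_log_two(self):
        ds = build_dataset(simple_rows({("s1", 5.0): 200.0,
                                        ("s1", 25.0): 200.0}))
        fc = fold_change(ds)
        assert fc["fc"].to_numpy() == pytest.approx(np.log(2))

    def test_doubling_then_halving_signs(self):
        ds = build_dataset(simple_rows({("s1", 5.0): 200.0,
                                        ("s1", 25.0): 50.0}))
        fc = fold_change(ds).set_index("time")["fc"]
        assert fc[5.0] > 0 > fc[25.0]

    def test_nonpositive_mfi_names_the_cell(self):
        ds = build_dataset(simple_rows({("s1", 5.0): -3.0,
                                        ("s1", 25.0): 10.0}))
        with pytest.raises(ValueError, match="s1"):
            fold_change(ds)


class TestCollapse:
    @pytest.mark.parametrize("fc5,fc25,expected", [
        (0.2, 0.9, 0.9),
        (0.2, -0.9, -0.9),
        (0.7, 0.7, 0.7),   # tie keeps the common value
        (-1.1, 0.3, -1.1),
    ])
    def test_max_magnitude_sign_preserved(self, fc5, fc25, expected):
        frame = pd.DataFrame({
            "donor": "d0", "stimulus": "s1", "readout": "R",
            "time": [5.0, 25.0], "fc": [fc5, fc25]})
        out = collapse_timepoints(frame)
        assert out["fc"].tolist() == [expected]

    def test_missing_both_timepoints_dropped(self):
        frame = pd.DataFrame({
            "donor": "d0", "stimulus": "s1", "readout": "R",
            "time": [5.0, 25.0], "fc": [np.nan, np.nan]})
        assert collapse_timepoints(frame).empty


class TestSignificanceFilter:
    @staticmethod
    def _collapsed(fcs, readout="R"):
        return pd.DataFrame({"donor": "d0",
                             "stimulus": [f"s{i}" for i in range(len(fcs))],
                             "readout": readout, "fc": fcs})

    def test_all_zero_fold_changes_non_significant(self):
        out = significance_filter(self._collapsed([0.0] * 6),
                                  pd.Series({"R": 0.1}),
                                  NormalizationParams())
        assert (out["state"] == NON_SIGNIFICANT).all()

    def test_single_extreme_value_called_by_sign_with_bh_oracle(self):
        fcs = [0.01, -0.02, 0.015, -1.0, 0.005]
        noise = pd.Series({"R": 0.1})
        out = significance_filter(self._collapsed(fcs), noise,
                                  NormalizationParams(fdr_q=0.05))
        # hand BH: sorted p, compare to i/m * q stepping up
        p = 2 * stats.norm.sf(np.abs(np.array(fcs) / 0.1))
        order = np.argsort(p)
        passed = np.zeros(len(p), dtype=bool)
        k = 0
        for rank, i in enumerate(order, start=1):
            if p[i] <= rank / len(p) * 0.05:
                k = rank
        passed[order[:k]] = True
        assert out["state"].tolist() == [
            DEPHOSPHORYLATED if (flag and f < 0) else
            PHOSPHORYLATED if (flag and f > 0) else NON_SIGNIFICANT
            for flag, f in zip(passed, fcs)]
        assert out.loc[3, "state"] == DEPHOSPHORYLATED

    def test_zero_mad_with_nonzero_fc_flagged_with_warning(self):
        with pytest.warns(UserWarning, match="zero control spread"):
            out = significance_filter(self._collapsed([0.5, 0.0]),
                                      pd.Series({"R": 0.0}),
                                      NormalizationParams())
        assert out["state"].tolist() == [PHOSPHORYLATED, NON_SIGNIFICANT]

    def test_control_noise_requires_three_values(self, tiny_cohort):
        _, _, _, cohort = tiny_cohort
        one_donor = cohort.data[cohort.data["donor"] == cohort.donors[0]]
        ds = PerturbationDataset(data=one_donor)
        with pytest.raises(ValueError, match="fewer than 3"):
            control_noise(ds)  # 2 control values per readout for one donor


class TestHill:
    def test_half_effect_at_ec50(self):
        assert hill(np.array([2.0]), ec50=2.0, k=2.0)[0] == pytest.approx(0.5)

    def test_zero_fold_change_maps_to_zero(self):
        assert hill(np.array([0.0]), ec50=1.0, k=2.0)[0] == 0.0

    def test_monotone_and_saturating(self):
        x = np.linspace(0, 50, 200)
        v = hill(x, ec50=1.0, k=2.0)
        assert np.all(np.diff(v) > 0)
        assert v[-1] < 1.0 and v[-1] > 0.99

    def test_states_map_to_value_conventions(self):
        stated = pd.DataFrame({
            "donor": "d0", "stimulus": ["a", "b", "c"], "readout": "R",
            "fc": [1.0, -1.0, 0.3],
            "state": [PHOSPHORYLATED, DEPHOSPHORYLATED, NON_SIGNIFICANT]})
        out = hill_normalize(stated, NormalizationParams(ec50=1.0)).table
        assert out["value"].tolist()[0] == pytest.approx(0.5)
        assert out["value"].tolist()[1] == 0.0
        assert np.isnan(out["value"].tolist()[2])


class TestPipelineProperties:
    def test_values_in_unit_interval(self, tiny_cohort):
        _, _, _, cohort = tiny_cohort
        norm = normalize_dataset(cohort)
        vals = norm.table["value"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_scaling_all_mfi_leaves_output_unchanged(self, tiny_cohort):
        _, _, _, cohort = tiny_cohort
        norm1 = normalize_dataset(cohort)
        scaled = PerturbationDataset(
            data=cohort.data.assign(value=cohort.data["value"] * 37.5),
            control_name=cohort.control_name)
        norm2 = normalize_dataset(scaled)
        pd.testing.assert_frame_equal(norm1.table, norm2.table)

    def test_noise_free_responders_hit_hill_of_log_effect(self, tiny_cohort):
        _, _, _, cohort = tiny_cohort
        params = NormalizationParams(ec50=0.7)
        norm = normalize_dataset(cohort, params)
        responding = norm.table.dropna(subset=["value"])
        responding = responding[responding["state"] == PHOSPHORYLATED]
        expected = hill(np.array([np.log(4.0)]), 0.7, params.hill_k)[0]
        assert responding["value"].to_numpy() == pytest.approx(expected)
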