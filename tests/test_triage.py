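import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from brute_oracle import brute_force_labels
from conftest import random_feature_table
from salixfate import synthetic_data as sd
from salixfate import triage
from salixfate.io import Channel
from salixfate.triage import FateLabel, FateRecord, RatioTest


def rt(ratio, p, t=0.0, df=4, undefined=False, insufficient=False):
    return RatioTest(ratio=ratio, t_statistic=t, p_value=p, df=df,
                     undefined=undefined, insufficient=insufficient)


ALL_PRESENT = {"t0": True, "t4": True, "t24": True}


@pytest.fixture()
def table():
    specs = sd.demo_features(seed=0)[:3]
    table, _ = sd.simulate_experiment(specs, noise_sigma=0.1, lod=100.0, seed=2)
    return table


class TestGroupStats:
    def test_full_triplicate(self, table):
        fid = table.feature_ids[0]
        samples = table.cell_samples(Channel.HFS_WBE, 2.0, 0.5)
        table.areas.loc[fid, samples] = [10.0, 12.0, 14.0]
        gs = triage.group_stats(table, fid, Channel.HFS_WBE, 2.0, 0.5)
        assert (gs.mean, gs.sd, gs.n_detected, gs.n_total) == (12.0, 2.0, 3, 3)
        assert gs.present()

    def test_not_detected_counts_as_zero(self, table):
        fid = table.feature_ids[0]
        samples = table.cell_samples(Channel.HFS_WBE, 2.0, 4.0)
        table.areas.loc[fid, samples] = [10.0, np.nan, 14.0]
        gs = triage.group_stats(table, fid, Channel.HFS_WBE, 2.0, 4.0)
        assert gs.mean == 8.0
        assert gs.n_detected == 2
        assert gs.present()

    def test_single_detection_is_not_present(self, table):
        fid = table.feature_ids[0]
        samples = table.cell_samples(Channel.HFS_WBE, 2.0, 24.0)
        table.areas.loc[fid, samples] = [np.nan, np.nan, 9.0]
        gs = triage.group_stats(table, fid, Channel.HFS_WBE, 2.0, 24.0)
        assert gs.n_detected == 1
        assert not gs.present()

    def test_unknown_cell_raises(self, table):
        with pytest.raises(KeyError):
            triage.group_stats(table, table.feature_ids[0], Channel.HFS_WBE, 5.0, 0.5)


class TestFoldTest:
    def test_identical_groups(self):
        result = triage.fold_test([1, 2, 3], [1, 2, 3])
        assert (result.ratio, result.t_statistic, result.p_value) == (1.0, 0.0, 1.0)

    def test_hand_computed_pooled_t(self):
        result = triage.fold_test([10, 12, 14], [20, 22, 24])
        assert result.ratio == pytest.approx(1.8333, rel=1e-4)
        assert abs(result.t_statistic) == pytest.approx(6.124, rel=1e-3)
        assert result.df == 4
        assert result.p_value == pytest.approx(0.00357, rel=1e-2)

    def test_swap_symmetry(self):
        a, b = [3.0, 5.0, 4.0], [9.0, 11.0, 13.0]
        fwd = triage.fold_test(a, b)
        rev = triage.fold_test(b, a)
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio)
        assert rev.t_statistic == pytest.approx(-fwd.t_statistic)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_insufficient_group_size_signalled(self):
        result = triage.fold_test([1.0], [1.0, 2.0, 3.0])
        assert result.insufficient

    def test_zero_variance_limits(self):
        equal = triage.fold_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert (equal.t_statistic, equal.p_value) == (0.0, 1.0)
        different = triage.fold_test([5.0, 5.0, 5.0], [8.0, 8.0, 8.0])
        assert different.p_value == 0.0
        assert different.t_statistic == math.inf

    def test_zero_denominator_ratios(self):
        formed = triage.fold_test([0.0, 0.0, 0.0], [10.0, 12.0, 11.0])
        assert formed.ratio == math.inf and not formed.undefined
        silent = triage.fold_test([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        assert silent.undefined

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=3, max_size=6),
        st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=3, max_size=6),
    )
    def test_matches_scipy_student_t(self, a, b):
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            return  # degenerate limit handled by test_zero_variance_limits
        result = triage.fold_test(a, b)
        oracle = stats.ttest_ind(b, a, equal_var=True)
        assert result.t_statistic == pytest.approx(float(oracle.statistic), abs=1e-9, rel=1e-9)
        assert result.p_value == pytest.approx(float(oracle.pvalue), abs=1e-9)


class TestClassifyFate:
    def test_increasing_rule(self):
        tests = {"t24_vs_t0": rt(3.0, 0.01), "t4_vs_t0": rt(1.2, 0.5), "t4_vs_t24": rt(0.6, 0.5)}
        assert triage.classify_fate(tests, ALL_PRESENT) is FateLabel.INCREASING

    def test_decreasing_rule(self):
        tests = {"t24_vs_t0": rt(0.4, 0.01), "t4_vs_t0": rt(0.8, 0.3), "t4_vs_t24": rt(2.0, 0.2)}
        assert triage.classify_fate(tests, ALL_PRESENT) is FateLabel.DECREASING

    def test_intermediate_takes_precedence(self):
        tests = {
            "t4_vs_t0": rt(2.5, 0.01),
            "t4_vs_t24": rt(1.5, 0.2),
            "t24_vs_t0": rt(2.2, 0.01),
        }
        assert triage.classify_fate(tests, ALL_PRESENT) is FateLabel.INTERMEDIATE

    def test_insignificant_ratio_is_unchanged(self):
        tests = {"t24_vs_t0": rt(3.0, 0.2), "t4_vs_t0": rt(1.0, 0.9), "t4_vs_t24": rt(1.0, 0.9)}
        assert triage.classify_fate(tests, ALL_PRESENT) is FateLabel.UNCHANGED

    def test_presence_gates_direction_claims(self):
        tests = {"t24_vs_t0": rt(3.0, 0.01)}
        absent_end = {"t0": True, "t4": True, "t24": False}
        assert triage.classify_fate(tests, absent_end) is FateLabel.UNCHANGED

    def test_all_insufficient(self):
        assert (
            triage.classify_fate({}, {"t0": False, "t4": False, "t24": False})
            is FateLabel.INSUFFICIENT_DATA
        )


class TestControlRules:
    def make_table(self, rows):
        """rows: feature -> {(channel, conc, time): triplicate areas} minimal table."""
        from salixfate.io import FeatureTable, make_design

        design = make_design()
        ids = list(rows)
        areas = pd.DataFrame(np.nan, index=pd.Index(ids, name="feature_id"), columns=design.index)
        for fid, cells in rows.items():
            for (ch, conc, t), values in cells.items():
                d = design
                cols = d.index[
                    (d["channel"] == ch)
                    & (d["wbe_concentration"].astype(float) == conc)
                    & (d["time_h"].astype(float) == t)
                ]
                areas.loc[fid, cols] = values
        features = pd.DataFrame({"mz": 300.0, "rt": 10.0}, index=areas.index)
        return FeatureTable(features=features, areas=areas, design=design)

    def test_matrix_filter(self):
        table = self.make_table(
            {
                "in_vehicle": {("HFS_VEHICLE", 0.0, 0.5): [5.0, 6.0, 7.0]},
                "only_extract_control": {("EXTRACT_CONTROL", 10.0, 0.5): [5.0, 6.0, 7.0]},
                "absent": {},
            }
        )
        assert triage.matrix_filter(table, "in_vehicle")
        assert not triage.matrix_filter(table, "only_extract_control")
        assert not triage.matrix_filter(table, "absent")

    def test_fast_metabolized_detection(self):
        table = self.make_table(
            {
                "fast": {("EXTRACT_CONTROL", 10.0, 0.5): [100.0, 110.0, 90.0]},
                "in_hfs": {
                    ("EXTRACT_CONTROL", 10.0, 0.5): [100.0, 110.0, 90.0],
                    ("HFS_WBE", 2.0, 0.5): [50.0, 60.0, 55.0],
                },
                "never_seen": {},
            }
        )
        assert triage.detect_fast_metabolized(table, "fast")
        assert not triage.detect_fast_metabolized(table, "in_hfs")
        assert not triage.detect_fast_metabolized(table, "never_seen")

    def test_crosscheck_abiotic_directions(self):
        def record(label):
            return FateRecord(feature_id="F", concentration=2.0, label=label)

        assert triage.crosscheck_abiotic(record(FateLabel.DECREASING), record(FateLabel.DECREASING))
        assert triage.crosscheck_abiotic(record(FateLabel.INCREASING), record(FateLabel.INCREASING))
        assert not triage.crosscheck_abiotic(record(FateLabel.DECREASING), record(FateLabel.UNCHANGED))
        assert not triage.crosscheck_abiotic(record(FateLabel.INCREASING), record(FateLabel.DECREASING))


class TestRunTriage:
    def test_noiseless_substrate_decreases_at_both_concentrations(self):
        spec = sd.FeatureSpec(
            "F1", 300.0, 10.0,
            sd.KineticArchetype(kind=sd.ArchetypeKind.SUBSTRATE, amplitude=1e6, k1=0.2),
        )
        table, _ = sd.simulate_experiment([spec], noise_sigma=0.0, lod=100.0, seed=1)
        records = triage.run_triage(table)
        assert {r.concentration for r in records} == {2.0, 10.0}
        assert all(r.label is FateLabel.DECREASING for r in records)

    def test_noiseless_matrix_feature(self):
        spec = sd.FeatureSpec(
            "F1", 300.0, 10.0,
            sd.KineticArchetype(kind=sd.ArchetypeKind.MATRIX, amplitude=1e6),
        )
        table, _ = sd.simulate_experiment([spec], noise_sigma=0.0, lod=100.0, seed=1)
        assert all(r.label is FateLabel.MATRIX for r in triage.run_triage(table))

    def test_deterministic_rerun(self):
        specs = sd.demo_features(seed=4)
        table, _ = sd.simulate_experiment(specs, noise_sigma=0.2, lod=100.0, seed=4)
        frame1 = triage.fates_to_frame(triage.run_triage(table))
        frame2 = triage.fates_to_frame(triage.run_triage(table))
        pd.testing.assert_frame_equal(frame1, frame2)

    def test_partition_one_label_per_feature_and_concentration(self):
        rng = np.random.default_rng(11)
        table = random_feature_table(rng, n_features=12)
        records = triage.run_triage(table)
        keys = [(r.feature_id, r.concentration) for r in records]
        assert len(keys) == len(set(keys)) == 12 * 2
        assert all(isinstance(r.label, FateLabel) for r in records)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, factor):
        rng = np.random.default_rng(21)
        table = random_feature_table(rng, n_features=6)
        base = [(r.feature_id, r.concentration, r.label, r.abiotic_flag)
                for r in triage.run_triage(table)]
        scaled_table = type(table)(
            features=table.features, areas=table.areas * factor, design=table.design
        )
        scaled = [(r.feature_id, r.concentration, r.label, r.abiotic_flag)
                  for r in triage.run_triage(scaled_table)]
        assert base == scaled

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_rule_application(self, seed):
        rng = np.random.default_rng(1000 + seed)
        table = random_feature_table(rng, n_features=10)
        records = triage.run_triage(table)
        labels, flags = brute_force_labels(table)
        for r in records:
            assert r.label.value == labels[(r.feature_id, r.concentration)], r.feature_id
            assert r.abiotic_flag == flags[(r.feature_id, r.concentration)], r.feature_id
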