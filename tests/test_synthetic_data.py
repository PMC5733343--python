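import math

import numpy as np
import pandas as pd
import pytest

from salixfate import synthetic_data as sd
from salixfate.io import Channel, TIME_POINTS


def arch(kind, amplitude=1.0, k1=None, k2=None, inhibition=1.25):
    return sd.KineticArchetype(
        kind=sd.ArchetypeKind(kind),
        amplitude=amplitude,
        k1=k1,
        k2=k2,
        inhibition_factor_high_conc=inhibition,
    )


class TestTrajectory:
    def test_substrate_closed_form(self):
        a = arch("SUBSTRATE", amplitude=100.0, k1=0.2)
        for t, expected in [(0.5, 90.48), (4.0, 44.93), (24.0, 0.823)]:
            assert sd.trajectory(a, t) == pytest.approx(expected, rel=1e-3)

    def test_intermediate_series_closed_form(self):
        a = arch("INTERMEDIATE", amplitude=1.0, k1=0.3, k2=0.5)
        for t, expected in [(0.5, 0.1229), (4.0, 0.2488), (24.0, 0.00111)]:
            assert sd.trajectory(a, t) == pytest.approx(expected, rel=1e-3)
        # rise/fall signature in group ratios
        assert sd.trajectory(a, 4.0) / sd.trajectory(a, 0.5) == pytest.approx(2.02, rel=0.01)
        assert sd.trajectory(a, 4.0) / sd.trajectory(a, 24.0) == pytest.approx(224, rel=0.01)

    def test_intermediate_peak_time(self):
        a = arch("INTERMEDIATE", k1=0.3, k2=0.5)
        assert sd.intermediate_peak_time(a) == pytest.approx(2.554, rel=1e-3)
        t_peak = sd.intermediate_peak_time(a)
        assert sd.trajectory(a, t_peak) > sd.trajectory(a, t_peak - 0.1)
        assert sd.trajectory(a, t_peak) > sd.trajectory(a, t_peak + 0.1)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sd.trajectory(arch("SUBSTRATE", k1=0.2), -1.0)

    def test_archetype_validation(self):
        with pytest.raises(ValueError):
            arch("SUBSTRATE")  # missing rate
        with pytest.raises(ValueError):
            arch("INTERMEDIATE", k1=0.3, k2=0.3)  # equal rates
        with pytest.raises(ValueError):
            arch("STABLE", amplitude=-1.0)


class TestChannelLogic:
    def test_biotic_archetypes_flat_in_extract_control(self):
        spec = sd.FeatureSpec("F1", 300.0, 10.0, arch("SUBSTRATE", 100.0, k1=0.3))
        areas = [sd.expected_area(spec, Channel.EXTRACT_CONTROL, 10.0, t) for t in TIME_POINTS]
        assert areas == [100.0, 100.0, 100.0]
        product = sd.FeatureSpec("F2", 300.0, 10.0, arch("PRODUCT", 100.0, k1=0.3))
        assert all(
            sd.expected_area(product, Channel.EXTRACT_CONTROL, 10.0, t) == 0.0
            for t in TIME_POINTS
        )

    def test_abiotic_decays_in_extract_control(self):
        spec = sd.FeatureSpec("F1", 300.0, 10.0, arch("ABIOTIC_UNSTABLE", 100.0, k1=0.2))
        areas = [sd.expected_area(spec, Channel.EXTRACT_CONTROL, 10.0, t) for t in TIME_POINTS]
        assert areas[0] > areas[1] > areas[2]
        assert areas == [
            sd.expected_area(spec, Channel.HFS_WBE, 10.0, t) for t in TIME_POINTS
        ]

    def test_matrix_present_in_all_fecal_channels_only(self):
        spec = sd.FeatureSpec("F1", 300.0, 10.0, arch("MATRIX", 50.0))
        for ch in (Channel.HFS_WBE, Channel.HFS_VEHICLE, Channel.HFS_PBS):
            assert sd.expected_area(spec, ch, 0.0, 4.0) == 50.0
        assert sd.expected_area(spec, Channel.EXTRACT_CONTROL, 10.0, 4.0) == 0.0

    def test_extract_features_absent_from_vehicle_and_pbs(self):
        spec = sd.FeatureSpec("F1", 300.0, 10.0, arch("SUBSTRATE", 100.0, k1=0.3))
        assert sd.expected_area(spec, Channel.HFS_VEHICLE, 0.0, 0.5) == 0.0
        assert sd.expected_area(spec, Channel.HFS_PBS, 0.0, 0.5) == 0.0

    def test_high_concentration_inhibition_slows_biotic_decay(self):
        spec = sd.FeatureSpec("F1", 300.0, 10.0, arch("SUBSTRATE", 100.0, k1=0.3, inhibition=2.0))
        low = sd.expected_area(spec, Channel.HFS_WBE, 2.0, 4.0)
        high = sd.expected_area(spec, Channel.HFS_WBE, 10.0, 4.0)
        assert high == pytest.approx(100.0 * math.exp(-0.15 * 4.0))
        assert high > low


class TestSimulateExperiment:
    def test_noiseless_areas_equal_trajectories(self):
        specs = sd.demo_features(seed=0)[:5]
        table, _ = sd.simulate_experiment(specs, noise_sigma=0.0, lod=0.0, seed=1)
        for spec in specs:
            for sid, row in table.design.iterrows():
                expected = sd.expected_area(
                    spec, Channel(row["channel"]), float(row["wbe_concentration"]),
                    float(row["time_h"]),
                )
                observed = table.areas.loc[spec.feature_id, sid]
                assert observed == pytest.approx(expected, rel=1e-12)

    def test_same_seed_bit_identical(self):
        specs = sd.study_features(n_substrate=5, n_product=5, n_intermediate=5,
                                  n_stable=5, n_abiotic=5, n_matrix=2, n_fast=1, seed=3)
        t1, _ = sd.simulate_experiment(specs, noise_sigma=0.2, lod=100.0, seed=42)
        t2, _ = sd.simulate_experiment(specs, noise_sigma=0.2, lod=100.0, seed=42)
        pd.testing.assert_frame_equal(t1.areas, t2.areas)
        t3, _ = sd.simulate_experiment(specs, noise_sigma=0.2, lod=100.0, seed=43)
        assert not t1.areas.equals(t3.areas)

    def test_lod_censoring_records_not_detected(self):
        specs = [sd.FeatureSpec("F1", 300.0, 10.0, arch("SUBSTRATE", 1e4, k1=0.5))]
        table, _ = sd.simulate_experiment(specs, noise_sigma=0.0, lod=100.0, seed=1)
        t24 = table.cell_areas("F1", Channel.HFS_WBE, 2.0, 24.0)
        assert np.isnan(t24).all()  # 1e4 * exp(-0.5*24) ~ 0.06 < LOD
        t0 = table.cell_areas("F1", Channel.HFS_WBE, 2.0, 0.5)
        assert not np.isnan(t0).any()

    def test_seed_required_and_config_validated(self):
        specs = sd.demo_features(seed=0)[:2]
        with pytest.raises(ValueError):
            sd.simulate_experiment(specs, seed=None)
        with pytest.raises(ValueError):
            sd.simulate_experiment(specs, noise_sigma=-0.1, seed=1)
        with pytest.raises(ValueError):
            sd.simulate_experiment(specs, lod=-5.0, seed=1)

    def test_truth_yaml_round_trip(self, tmp_path):
        specs = sd.demo_features(seed=0)[:8]
        _, truth = sd.simulate_experiment(specs, noise_sigma=0.1, lod=100.0, seed=9)
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        loaded = sd.SyntheticTruth.from_yaml(path)
        assert loaded.seed == truth.seed
        assert loaded.sigma == truth.sigma
        for fid, spec in truth.features.items():
            other = loaded.features[fid]
            assert other == spec  # frozen dataclasses: bit-identical fields


class TestExpectedLabelOracle:
    def test_canonical_archetype_labels(self):
        specs = sd.study_features(n_substrate=2, n_product=2, n_intermediate=2,
                                  n_stable=2, n_abiotic=2, n_matrix=1, n_fast=1, seed=5)
        _, truth = sd.simulate_experiment(specs, noise_sigma=0.0, lod=100.0, seed=5)
        expected_by_kind = {
            "SUBSTRATE": "DECREASING",
            "PRODUCT": "INCREASING",
            "INTERMEDIATE": "INTERMEDIATE",
            "STABLE": "UNCHANGED",
            "ABIOTIC_UNSTABLE": "DECREASING",
            "MATRIX": "MATRIX",
        }
        for spec in specs:
            kind = spec.archetype.kind.value
            expected = expected_by_kind[kind]
            if kind == "SUBSTRATE" and spec.archetype.k1 == 40.0:
                expected = "FAST_METABOLIZED"
            for conc in (2.0, 10.0):
                assert truth.expected_label(spec.feature_id, conc) == expected, (
                    spec.feature_id, kind, conc,
                )

    def test_abiotic_flag_expectation(self):
        specs = sd.study_features(n_substrate=1, n_product=0, n_intermediate=0,
                                  n_stable=0, n_abiotic=1, n_matrix=0, n_fast=0, seed=6)
        _, truth = sd.simulate_experiment(specs, noise_sigma=0.0, lod=100.0, seed=6)
        kinds = {s.feature_id: s.archetype.kind.value for s in specs}
        for fid, kind in kinds.items():
            assert truth.expected_abiotic_flag(fid) == (kind == "ABIOTIC_UNSTABLE")
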