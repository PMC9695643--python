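"""Dose metrics: exact hand-computed values on synthetic fields."""

import numpy as np
import pytest

from phototherm import dose_metrics as dm
from phototherm import phantom as pm


@pytest.fixture(scope="module")
def small_phantom():
    return pm.build_phantom(1.0, fv_label=1e-6)


def field_with(phantom, tumor_temp, normal_temp):
    f = np.full(phantom.shape, normal_temp, dtype=float)
    f[phantom.tumor_mask] = tumor_temp
    return f


class TestApoptosisRatio:
    def test_baseline_field_scores_zero(self, small_phantom):
        f = field_with(small_phantom, 37.0, 37.0)
        assert dm.apoptosis_ratio(f, small_phantom.tumor_mask) == 0.0

    def test_whole_tumor_in_band_scores_one(self, small_phantom):
        f = field_with(small_phantom, 45.0, 37.0)
        assert dm.apoptosis_ratio(f, small_phantom.tumor_mask) == 1.0

    def test_half_tumor_in_band_scores_half(self, small_phantom):
        f = field_with(small_phantom, 37.0, 37.0)
        idx = np.argwhere(small_phantom.tumor_mask)
        half = idx[: len(idx) // 2]
        f[half[:, 0], half[:, 1], half[:, 2]] = 45.0
        expected = len(half) / len(idx)
        assert dm.apoptosis_ratio(f, small_phantom.tumor_mask) == pytest.approx(expected, abs=1e-15)

    def test_band_edges_half_open(self, small_phantom):
        f43 = field_with(small_phantom, 43.0, 37.0)
        f50 = field_with(small_phantom, 50.0, 37.0)
        assert dm.apoptosis_ratio(f43, small_phantom.tumor_mask) == 1.0
        assert dm.apoptosis_ratio(f50, small_phantom.tumor_mask) == 0.0

    def test_permutation_invariance(self, small_phantom):
        rng = np.random.default_rng(1)
        f = field_with(small_phantom, 37.0, 37.0)
        temps = rng.uniform(37, 55, small_phantom.tumor_mask.sum())
        f[small_phantom.tumor_mask] = temps
        r1 = dm.apoptosis_ratio(f, small_phantom.tumor_mask)
        f[small_phantom.tumor_mask] = rng.permutation(temps)
        assert dm.apoptosis_ratio(f, small_phantom.tumor_mask) == r1

    def test_empty_mask_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            dm.apoptosis_ratio(np.full(small_phantom.shape, 37.0),
                               np.zeros(small_phantom.shape, dtype=bool))


class TestThermalHazard:
    band = dm.BAND_HAZARD

    def test_baseline_scores_zero_under_both_weightings(self, small_phantom):
        f = field_with(small_phantom, 37.0, 37.0)
        for w in (dm.BAND_HAZARD, dm.GRADED_HAZARD):
            assert dm.thermal_hazard(f, small_phantom.normal_mask, w) == 0.0

    def test_all_normal_tissue_in_band_scores_one(self, small_phantom):
        f = field_with(small_phantom, 37.0, 45.0)
        for w in (dm.BAND_HAZARD, dm.GRADED_HAZARD):
            assert dm.thermal_hazard(f, small_phantom.normal_mask, w) == 1.0

    def test_half_necrotic_half_baseline(self, small_phantom):
        f = field_with(small_phantom, 37.0, 37.0)
        idx = np.argwhere(small_phantom.normal_mask)
        half = idx[: len(idx) // 2]
        f[half[:, 0], half[:, 1], half[:, 2]] = 52.0
        expected = 2.0 * len(half) / len(idx)  # weight 2 above 50 deg C
        for w in (dm.BAND_HAZARD, dm.GRADED_HAZARD):
            assert dm.thermal_hazard(f, small_phantom.normal_mask, w) == pytest.approx(expected, abs=1e-15)

    def test_graded_weighting_counts_hyperthermia(self, small_phantom):
        f = field_with(small_phantom, 37.0, 40.0)
        assert dm.thermal_hazard(f, small_phantom.normal_mask, dm.BAND_HAZARD) == 0.0
        assert dm.thermal_hazard(f, small_phantom.normal_mask, dm.GRADED_HAZARD) == pytest.approx(0.1)

    def test_monotone_under_pointwise_heating(self, small_phantom):
        rng = np.random.default_rng(2)
        f = field_with(small_phantom, 37.0, 37.0)
        f[small_phantom.normal_mask] = rng.uniform(37, 55, small_phantom.normal_mask.sum())
        h1 = dm.thermal_hazard(f, small_phantom.normal_mask, dm.GRADED_HAZARD)
        h2 = dm.thermal_hazard(f + 1.5, small_phantom.normal_mask, dm.GRADED_HAZARD)
        assert h2 >= h1

    def test_invalid_weighting_rejected(self):
        with pytest.raises(ValueError):
            dm.HazardWeighting("bad", (50.0, 43.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            dm.HazardWeighting("bad", (43.0,), (1.0, 2.0))
        with pytest.raises(ValueError):
            dm.HazardWeighting("bad", (43.0, 50.0), (-1.0, 2.0))


class TestRetentionAverage:
    def test_constant_trace(self):
        t = np.linspace(0, 900, 901)
        assert dm.retention_average(t, np.full(901, 0.37)) == pytest.approx(0.37, rel=1e-12)

    def test_half_on_half_off(self):
        t = np.array([0.0, 450.0, 450.0 + 1e-9, 900.0])
        v = np.array([1.0, 1.0, 0.0, 0.0])
        assert dm.retention_average(t, v) == pytest.approx(0.5, abs=1e-9)

    def test_linear_ramp_averages_half(self):
        t = np.linspace(0, 900, 901)
        assert dm.retention_average(t, t / 900.0) == pytest.approx(0.5, rel=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            dm.retention_average(np.array([]), np.array([]))


class TestEffectiveRatio:
    def test_zero_dose_is_zero(self):
        assert dm.effective_ratio(0.0, 5.0) == 0.0

    def test_plain_division(self):
        assert dm.effective_ratio(0.4, 0.2) == pytest.approx(2.0, rel=1e-12)

    def test_zero_hazard_guard(self):
        assert dm.effective_ratio(0.1, 0.0, eps=1e-3) == pytest.approx(100.0, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm.effective_ratio(-0.1, 0.2)


class TestSeriesEvaluation:
    def test_synthetic_series_metrics_match_hand_computation(self, small_phantom):
        spec = pm.SyntheticFieldSpec(
            45.0, 37.0, (0.0, 0.0, 1.1), 30.0,
            ((0.0, 1.0), (300.0, 1.0), (300.0 + 1e-6, 0.0), (900.0, 0.0)),
        )
        series = pm.synth_temperature_series(spec, small_phantom)
        ms = dm.evaluate_series(series, small_phantom, weighting=dm.BAND_HAZARD,
                                condition={"P_mw": 0.0})
        # hot sphere covers everything: thetaA=1, thetaH=1 for first third
        assert ms.theta_a[0] == 1.0 and ms.theta_h[0] == 1.0
        assert ms.theta_a[-1] == 0.0 and ms.theta_h[-1] == 0.0
        assert ms.theta_a_star == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert ms.theta_h_star == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert ms.theta_eff_star == pytest.approx(1.0, abs=1e-5)

    def test_band_retention_over_powers_matches_direct_evaluation(self, small_phantom):
        """The sorted/binary-search fast path equals per-power recomputation."""
        rng = np.random.default_rng(3)
        times = np.linspace(0, 60, 61)
        m = 500
        unit = rng.gamma(2.0, 0.02, size=(61, m))  # unit-power rises
        powers = np.array([0.0, 40.0, 200.0, 640.0])
        got = dm.band_retention_over_powers(times, unit, 37.0, powers, (43.0, 50.0), (1.0, 0.0))
        for i, p in enumerate(powers):
            t_field = 37.0 + p * unit
            frac = np.count_nonzero((t_field >= 43.0) & (t_field < 50.0), axis=1) / m
            direct = dm.retention_average(times, frac)
            assert got[i] == pytest.approx(direct, abs=1e-12)
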