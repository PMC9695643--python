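"""Bioheat solver: schedule logic, stability, conservation, closed forms."""

import math

import numpy as np
import pytest

from phototherm import bioheat as bh
from phototherm import phantom as pm

from conftest import gaussian_blob_map


class TestSchedule:
    def test_continuous_heating_always_on(self):
        s = bh.TreatmentSchedule(phi_c=0.0)
        assert all(bh.laser_on(t, s) for t in (0.0, 29.9, 30.0, 45.0, 899.0))

    def test_equal_cooling_cycle(self):
        s = bh.TreatmentSchedule(phi_c=1.0)
        assert bh.laser_on(15.0, s)
        assert not bh.laser_on(45.0, s)  # cycle 60 s: on 0-30, off 30-60
        assert bh.laser_on(60.0, s)

    def test_cooling_fraction_relation(self):
        from phototherm.sweep import cooling_fraction

        assert cooling_fraction(0.0) == 0.0
        assert cooling_fraction(1.0) == 0.5
        assert cooling_fraction(2.33) == pytest.approx(0.6997, abs=5e-5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bh.laser_on(-1.0, bh.TreatmentSchedule())


class TestStableDt:
    def test_homogeneous_closed_form(self):
        ph = pm.homogeneous_phantom((4, 4, 4), 1.0, mua=0.1, mus=1.0, g=0.5,
                                    rho=1000.0, c_v=4000.0, k=0.5)
        # rho c d^2 / (6 k) = 4e6 * 1e-6 / 3
        assert bh.stable_dt(ph, 1.0) == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_halving_voxel_quarters_dt(self):
        a = pm.homogeneous_phantom((4, 4, 4), 1.0, 0.1, 1.0, 0.5)
        b = pm.homogeneous_phantom((4, 4, 4), 0.5, 0.1, 1.0, 0.5)
        assert bh.stable_dt(b, 1.0) == pytest.approx(bh.stable_dt(a, 1.0) / 4, rel=1e-12)

    def test_multimaterial_minimum_governs(self):
        ph = pm.build_phantom(1.0, fv_label=1e-6)
        per_layer = []
        for spec in list(pm.SKIN_LAYERS) + [pm.TUMOR_LAYER]:
            per_layer.append(spec.rho * spec.c_v * (1e-3) ** 2 / (6 * spec.k))
        assert bh.stable_dt(ph, 1.0) == pytest.approx(min(per_layer), rel=1e-12)


class TestStep:
    def test_uniform_field_without_source_unchanged(self):
        ph = pm.homogeneous_phantom((3, 3, 3), 1.0, 0.1, 1.0, 0.5)
        T = np.full(ph.shape, 37.0)
        out = bh.step(T, ph, None, 0.0, 0.05, on=False)
        assert np.array_equal(out, T)

    def test_two_voxel_exchange_closed_form(self):
        """Conduction term: dT = dt * (T_n - T) * k_face * A / (d * rho c V)."""
        ph = pm.homogeneous_phantom((2, 1, 1), 1.0, 0.1, 1.0, 0.5,
                                    rho=1000.0, c_v=4000.0, k=0.5)
        T = np.zeros(ph.shape)
        T[0], T[1] = 38.0, 36.0
        out = bh.step(T, ph, None, 0.0, 0.1, on=False)
        assert out[0, 0, 0] == pytest.approx(38.0 - 0.025, rel=1e-12)
        assert out[1, 0, 0] == pytest.approx(36.0 + 0.025, rel=1e-12)
        assert out.sum() == pytest.approx(T.sum(), rel=1e-14)

    def test_maximum_principle_without_source(self):
        ph = pm.homogeneous_phantom((5, 5, 5), 1.0, 0.1, 1.0, 0.5)
        rng = np.random.default_rng(0)
        T = 37.0 + rng.uniform(-2, 5, ph.shape)
        lo, hi = T.min(), T.max()
        for _ in range(20):
            T = bh.step(T, ph, None, 0.0, 0.2, on=False)
            assert T.min() >= lo - 1e-12 and T.max() <= hi + 1e-12

    def test_unstable_dt_rejected(self):
        ph = pm.homogeneous_phantom((3, 3, 3), 1.0, 0.1, 1.0, 0.5)
        with pytest.raises(ValueError):
            bh.step(np.full(ph.shape, 37.0), ph, None, 0.0, 10.0, on=False)


class TestRun:
    def test_zero_power_keeps_initial_field(self):
        ph = pm.homogeneous_phantom((4, 4, 4), 1.0, 0.1, 1.0, 0.5)
        cfg = bh.SolverConfig(boundary="adiabatic", snapshot_interval=1.0)
        s = bh.run(ph, None, bh.TreatmentSchedule(tau_tot=5.0), 0.0, cfg)
        assert np.all(s.fields == 37.0)

    def test_adiabatic_energy_budget_exact(self):
        """Total energy gain equals power x absorbed fraction x on-time."""
        ph = pm.homogeneous_phantom((6, 6, 6), 1.0, 0.1, 1.0, 0.5)
        amap = gaussian_blob_map(ph, total=0.8)
        cfg = bh.SolverConfig(boundary="adiabatic")
        sched = bh.TreatmentSchedule(tau_tot=60.0, tau_h=30.0, phi_c=1.0)
        s = bh.run(ph, amap, sched, power_mw=100.0, config=cfg)
        cap = ph.rho * ph.c_v * ph.voxel_volume_mm3 * 1e-9
        gained = (cap * (s.fields[-1] - 37.0)).sum()
        on_time = s.meta["n_on_steps"] * s.meta["dt"]
        assert on_time == pytest.approx(30.0, abs=s.meta["dt"] / 2)
        expect = 100e-3 * 0.8 * on_time
        assert gained == pytest.approx(expect, rel=1e-6)

    def test_superposition_linearity_in_power(self):
        """T(P) - T0 is homogeneous of degree one in laser power."""
        ph = pm.homogeneous_phantom((6, 6, 6), 1.0, 0.1, 1.0, 0.5)
        amap = gaussian_blob_map(ph, total=0.8)
        sched = bh.TreatmentSchedule(tau_tot=20.0, tau_h=30.0, phi_c=0.0)
        s1 = bh.run(ph, amap, sched, 1.0)
        s5 = bh.run(ph, amap, sched, 5.0)
        r1 = s1.fields[-1] - 37.0
        r5 = s5.fields[-1] - 37.0
        assert np.allclose(r5, 5.0 * r1, rtol=1e-8, atol=1e-10)

    def test_point_deposit_spreads_like_heat_kernel(self):
        """Short central deposit matches the analytic Gaussian kernel to 3 %.

        Mid-domain times: late enough that the voxel-cube deposit looks
        point-like against the spread (sigma ~ 4.5 voxels), early enough
        that adiabatic walls have not reflected the pulse.
        """
        n = 41
        ph = pm.homogeneous_phantom((n, n, n), 0.5, 0.1, 1.0, 0.5,
                                    rho=1000.0, c_v=4000.0, k=0.5)
        a = np.zeros(ph.shape)
        a[n // 2, n // 2, n // 2] = 1.0
        amap = gaussian_blob_map(ph)
        amap.a = a
        sched = bh.TreatmentSchedule(tau_tot=20.0, tau_h=0.25, phi_c=79.0)
        cfg = bh.SolverConfig(boundary="adiabatic", snapshot_interval=0.5)
        s = bh.run(ph, amap, sched, power_mw=1000.0, config=cfg)
        on_time = s.meta["n_on_steps"] * s.meta["dt"]
        q_joule = 1.0 * on_time  # 1000 mW for the pulse
        rho_c = 1000.0 * 4000.0
        alpha = 0.5 / rho_c
        cx, cy, cz = ph.centers()
        mid = cx[n // 2]
        r2 = (
            (cx[:, None, None] - mid) ** 2
            + (cy[None, :, None] - mid) ** 2
            + (cz[None, None, :] - cz[n // 2]) ** 2
        ) * 1e-6  # m^2
        for t_idx in (38, 40):  # t = 19, 20 s
            t_eff = s.times[t_idx] - on_time / 2
            kernel = (
                q_joule
                / (rho_c * (4 * math.pi * alpha * t_eff) ** 1.5)
                * np.exp(-r2 / (4 * alpha * t_eff))
            )
            got = s.fields[t_idx] - 37.0
            sel = kernel > 0.05 * kernel.max()
            rel = np.abs(got[sel] / kernel[sel] - 1.0)
            assert rel.max() < 0.03

    def test_divergence_raises_named_error(self):
        ph = pm.homogeneous_phantom((3, 3, 3), 1.0, 0.1, 1.0, 0.5)
        T = np.full(ph.shape, 37.0)
        T[1, 1, 1] = np.inf
        with pytest.raises(bh.SolverDivergedError):
            bh.step(T, ph, None, 0.0, 0.05, on=False)

    def test_monitor_traces_and_csv_export(self, tmp_path, coarse_phantom, coarse_map):
        cfg = bh.SolverConfig(snapshot_interval=1.0)
        sched = bh.TreatmentSchedule(tau_tot=10.0)
        s = bh.run(coarse_phantom, coarse_map, sched, 100.0, cfg,
                   record_mask=coarse_phantom.active,
                   monitor_points=(bh.TUMOR_MONITOR_MM, bh.NORMAL_MONITOR_MM))
        assert s.monitors.shape == (11, 2)
        assert np.all(np.diff(s.monitors[:, 0]) > 0)  # tumor point heats steadily
        out = tmp_path / "traces.csv"
        bh.export_monitor_csv(s, str(out))
        import pandas as pd

        df = pd.read_csv(out)
        assert list(df.columns) == ["time_s", "T_tumor_C", "T_normal_C"]
        assert len(df) == 11

    def test_masked_recording_matches_full_fields(self, coarse_phantom, coarse_map):
        sched = bh.TreatmentSchedule(tau_tot=5.0)
        full = bh.run(coarse_phantom, coarse_map, sched, 50.0)
        masked = bh.run(coarse_phantom, coarse_map, sched, 50.0,
                        record_mask=coarse_phantom.tumor_mask)
        assert np.allclose(
            masked.at_mask(coarse_phantom.tumor_mask),
            full.at_mask(coarse_phantom.tumor_mask),
        )
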