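"""Parametric treatment-condition study and optimum search.

The study grid crosses laser power (0–1000 mW in 20 mW steps), nanorod
volume fraction (1e-3 .. 1e-6) and cooling-time ratio (0 .. 2.33) at a
fixed 900 s treatment with 30 s heating intervals.  The expensive work
scales with (f_v, phi_c) only: one Monte Carlo absorption map per f_v
and one unit-power bioheat solve per (f_v, phi_c).  Because the heat
equation is linear in the source, the field at any power is
``baseline + P * unit_rise``, so all powers of the grid are evaluated
from each unit solve by scaling — 24 PDE solves cover the 1224-condition
grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bioheat, dose_metrics, phantom as phantom_mod, photon_mc

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "find_optimum",
    "cooling_fraction",
]

TABLE_POWERS_MW = np.arange(0.0, 1000.0 + 1e-9, 20.0)  # 51 values
TABLE_FV = (1e-3, 1e-4, 1e-5, 1e-6)
TABLE_PHI_C = (0.0, 0.5, 1.0, 1.5, 2.0, 2.33)


@dataclass(frozen=True)
class SweepGrid:
    """The condition grid: powers (mW), volume fractions, cooling ratios."""

    powers_mw: tuple[float, ...] = tuple(TABLE_POWERS_MW)
    f_v: tuple[float, ...] = TABLE_FV
    phi_c: tuple[float, ...] = TABLE_PHI_C

    def __post_init__(self) -> None:
        for name in ("powers_mw", "f_v", "phi_c"):
            vals = getattr(self, name)
            if len(vals) == 0 or len(set(vals)) != len(vals):
                raise ValueError(f"{name} must be non-empty without duplicates")

    @property
    def size(self) -> int:
        return len(self.powers_mw) * len(self.f_v) * len(self.phi_c)

    @classmethod
    def default(cls) -> "SweepGrid":
        return cls()

    def subset(self, powers_mw=None, f_v=None, phi_c=None) -> "SweepGrid":
        """Explicit reduced grid (values must belong to this grid)."""
        def pick(cur, req, name):
            if req is None:
                return cur
            req = tuple(req)
            if not set(req) <= set(cur):
                raise ValueError(f"{name} subset contains values outside the grid")
            return req

        return SweepGrid(
            powers_mw=pick(self.powers_mw, powers_mw, "powers_mw"),
            f_v=pick(self.f_v, f_v, "f_v"),
            phi_c=pick(self.phi_c, phi_c, "phi_c"),
        )


@dataclass(frozen=True)
class SweepConfig:
    """Fidelity and physics configuration of a sweep run.

    ``voxel_size`` is the thermal grid; ``mc_voxel_size`` the (finer)
    transport grid.  Light transport must resolve the 0.08 mm epidermis,
    whose scattering backscatters a quarter of the beam before it
    reaches the tumor; the absorption map is block-summed onto the
    thermal grid (energy conserving).  The ratio must be an integer.
    """

    voxel_size: float = 0.5
    mc_voxel_size: float = 0.1
    n_photons: int = 1_000_000
    seed: int = 0
    tau_tot: float = 900.0
    tau_h: float = 30.0
    snapshot_interval: float = 1.0
    initial_temp: float = 37.0
    solver_safety: float = 0.5
    band: dose_metrics.ApoptosisBand = dose_metrics.DEFAULT_BAND
    weighting: dose_metrics.HazardWeighting = dose_metrics.DEFAULT_HAZARD
    eps: float = dose_metrics.EPS_DEFAULT

    @classmethod
    def paper(cls, seed: int = 0) -> "SweepConfig":
        """Production fidelity: 0.5 mm thermal voxels, 1e6 photons per map."""
        return cls(voxel_size=0.5, mc_voxel_size=0.1, n_photons=1_000_000, seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "SweepConfig":
        """Fast desk-scale fidelity: 1.0 mm thermal voxels, 1e5 photons."""
        return cls(voxel_size=1.0, mc_voxel_size=0.1, n_photons=100_000, seed=seed)

    @property
    def mc_factor(self) -> int:
        f = self.voxel_size / self.mc_voxel_size
        if abs(f - round(f)) > 1e-9:
            raise ValueError("voxel_size must be an integer multiple of mc_voxel_size")
        return int(round(f))


@dataclass
class SweepResult:
    """Long-format per-condition metrics plus unit-power trace library."""

    records: pd.DataFrame
    unit_monitors: dict = field(default_factory=dict)  # (f_v, phi_c) -> (times, monitors)
    failures: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def monitor_trace(self, f_v: float, phi_c: float, power_mw: float):
        """Monitored-point temperature traces at a grid condition.

        Returns (times, temps) with temps of shape (n_t, 2): tumor point
        (axis, 0.1 mm) and normal point (axis, 2.5 mm), scaled from the
        unit-power solve.
        """
        times, unit = self.unit_monitors[(f_v, phi_c)]
        base = self.meta.get("initial_temp", 37.0)
        return times, base + power_mw * (unit - base)


def cooling_fraction(phi_c: float) -> float:
    """Fraction of the treatment spent cooling: phi_c / (1 + phi_c)."""
    if phi_c < 0:
        raise ValueError("phi_c must be non-negative")
    return phi_c / (1.0 + phi_c)


def run_sweep(grid: SweepGrid, config: SweepConfig = SweepConfig()) -> SweepResult:
    """Run the full study: trace per f_v, solve per (f_v, phi_c), scale per power.

    Failures in one condition are recorded and the sweep continues; the
    result is flagged partial via ``failures``.
    """
    powers = np.asarray(grid.powers_mw, dtype=float)
    rows = []
    unit_monitors: dict = {}
    failures: list = []
    monitor_pts = (bioheat.TUMOR_MONITOR_MM, bioheat.NORMAL_MONITOR_MM)
    band = config.band
    bp_a = (band.lower, band.upper)
    w_a = (1.0, 0.0)  # in-band counts, necrotic does not
    bp_h = config.weighting.breakpoints
    w_h = config.weighting.weights

    for fi, f_v in enumerate(grid.f_v):
        seed_fv = (int(config.seed) * 10_007 + fi) % (2**31)
        try:
            ph = phantom_mod.build_phantom(config.voxel_size, fv_label=f_v)
            src = photon_mc.LaserSource(power_mw=1.0)
            factor = config.mc_factor
            if factor == 1:
                amap = photon_mc.trace(ph, src, n_photons=config.n_photons, seed=seed_fv)
            else:
                ph_fine = phantom_mod.build_phantom(config.mc_voxel_size, fv_label=f_v)
                amap = photon_mc.downsample(
                    photon_mc.trace(ph_fine, src, n_photons=config.n_photons, seed=seed_fv),
                    factor,
                )
                del ph_fine
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("tracing failed for f_v=%g", f_v)
            failures.append({"f_v": f_v, "stage": "trace", "error": repr(exc)})
            continue
        logger.info(
            "f_v=%g: absorbed fraction %.4f (n=%d photons)",
            f_v, amap.absorbed_fraction, config.n_photons,
        )
        tumor = ph.tumor_mask
        normal = ph.normal_mask
        for phi_c in grid.phi_c:
            sched = bioheat.TreatmentSchedule(config.tau_tot, config.tau_h, phi_c)
            cfg = bioheat.SolverConfig(
                snapshot_interval=config.snapshot_interval,
                initial_temp=config.initial_temp,
                safety=config.solver_safety,
            )
            try:
                series = bioheat.run(
                    ph, amap, sched, power_mw=1.0, config=cfg,
                    record_mask=ph.active, monitor_points=monitor_pts,
                    dtype=np.float32,
                )
                u_tum = series.at_mask(tumor) - config.initial_temp
                u_nor = series.at_mask(normal) - config.initial_temp
                a_star = dose_metrics.band_retention_over_powers(
                    series.times, u_tum, config.initial_temp, powers, bp_a, w_a
                )
                h_star = dose_metrics.band_retention_over_powers(
                    series.times, u_nor, config.initial_temp, powers, bp_h, w_h
                )
            except Exception as exc:
                logger.exception("solve failed for f_v=%g phi_c=%g", f_v, phi_c)
                failures.append(
                    {"f_v": f_v, "phi_c": phi_c, "stage": "solve", "error": repr(exc)}
                )
                continue
            eff = a_star / np.maximum(h_star, config.eps)
            unit_monitors[(f_v, phi_c)] = (series.times, series.monitors.copy())
            for pi, p_mw in enumerate(powers):
                rows.append(
                    {
                        "P_mw": p_mw,
                        "f_v": f_v,
                        "phi_c": phi_c,
                        "thetaA_star": a_star[pi],
                        "thetaH_star": h_star[pi],
                        "thetaEff_star": eff[pi],
                    }
                )
            logger.info("f_v=%g phi_c=%g done (dt=%.4gs)", f_v, phi_c, series.meta["dt"])

    records = pd.DataFrame(rows)
    return SweepResult(
        records=records,
        unit_monitors=unit_monitors,
        failures=failures,
        meta={
            "seed": config.seed,
            "n_photons": config.n_photons,
            "voxel_size": config.voxel_size,
            "initial_temp": config.initial_temp,
            "weighting": config.weighting.name,
            "eps": config.eps,
            "grid_size": grid.size,
        },
    )


def find_optimum(
    result: SweepResult, metric: str = "thetaEff_star"
) -> tuple[float, float, float]:
    """Grid argmax of a metric; returns (P_mw, f_v, phi_c).

    Ties are broken toward lower power, then lower volume fraction, then
    lower cooling ratio, and logged.
    """
    if metric not in ("thetaA_star", "thetaEff_star", "thetaH_star"):
        raise ValueError(f"unknown metric {metric!r}")
    df = result.records
    if df is None or len(df) == 0:
        raise ValueError("empty sweep result")
    best = df[metric].max()
    ties = df[np.isclose(df[metric], best, rtol=0, atol=0)]
    if len(ties) > 1:
        logger.info("%d conditions tie at %s=%g; picking lowest (P, f_v, phi_c)", len(ties), metric, best)
    pick = ties.sort_values(["P_mw", "f_v", "phi_c"]).iloc[0]
    return float(pick["P_mw"]), float(pick["f_v"]), float(pick["phi_c"])
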