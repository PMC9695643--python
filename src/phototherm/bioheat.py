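"""Explicit finite-difference heat diffusion with the laser source term.

The temperature field obeys pure heat diffusion,

    rho c_v dT/dt = div(k grad T) + q,

with no perfusion term; the volumetric source q is the Monte Carlo
absorbed-fraction map scaled by the instantaneous laser power.  The
update is the standard explicit seven-point stencil with harmonic-mean
face conductivities 2 k k_n / (k + k_n), so fluxes are continuous across
layer interfaces.  Voxels outside the cylindrical domain are inactive:
no conduction crosses their faces.

Pulsed schedules are described by the heating time tau_h and the
cooling-time ratio phi_c (cooling interval = phi_c * tau_h); phi_c = 0
is continuous heating.  Temperatures are kept in degrees Celsius
(diffusion is offset-invariant); material properties are SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .photon_mc import AbsorptionMap

__all__ = [
    "TreatmentSchedule",
    "SolverConfig",
    "TemperatureSeries",
    "SolverDivergedError",
    "laser_on",
    "stable_dt",
    "step",
    "run",
    "export_monitor_csv",
    "TUMOR_MONITOR_MM",
    "NORMAL_MONITOR_MM",
]

#: On-axis monitoring points (x, y, z) in mm: inside the tumor just
#: below its top face (0.1 mm deep) and in normal tissue 0.4 mm beneath
#: the tumor's bottom face (2.5 mm deep).
TUMOR_MONITOR_MM = (0.0, 0.0, 0.1)
NORMAL_MONITOR_MM = (0.0, 0.0, 2.5)


class SolverDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TreatmentSchedule:
    """Pulsed laser timeline: total time, heating time, cooling ratio."""

    tau_tot: float = 900.0
    tau_h: float = 30.0
    phi_c: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_tot <= 0 or self.tau_h <= 0:
            raise ValueError("tau_tot and tau_h must be positive")
        if self.phi_c < 0:
            raise ValueError("phi_c must be non-negative")

    @property
    def cycle(self) -> float:
        """One heating+cooling period, s."""
        return self.tau_h * (1.0 + self.phi_c)


def laser_on(t: float, schedule: TreatmentSchedule) -> bool:
    """True iff the laser is on at time t (s) under the pulsed schedule."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if schedule.phi_c == 0:
        return True
    return (t % schedule.cycle) < schedule.tau_h


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs of the explicit solver.

    dt:
        Time step in s, or "auto" for the stability bound times
        ``safety`` (then rounded down so snapshots land on steps).
    snapshot_interval:
        Seconds between recorded fields (1 s resolves the 30 s pulses).
    initial_temp:
        Uniform initial and far-field temperature, deg C (body core).
    boundary:
        "fixed-far" — far lateral/bottom boundaries held at the initial
        temperature, top surface adiabatic (semi-infinite tissue);
        "adiabatic" — no heat leaves the domain at all (used for energy
        -budget verification).
    safety:
        Fraction of the explicit stability bound used when dt is auto.
    """

    dt: float | str = "auto"
    snapshot_interval: float = 1.0
    initial_temp: float = 37.0
    boundary: str = "fixed-far"
    safety: float = 0.5

    def __post_init__(self) -> None:
        if self.boundary not in ("fixed-far", "adiabatic"):
            raise ValueError("boundary must be 'fixed-far' or 'adiabatic'")
        if not 0.0 < self.safety <= 1.0:
            raise ValueError("safety must lie in (0, 1]")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")
        if self.dt != "auto" and (not isinstance(self.dt, (int, float)) or self.dt <= 0):
            raise ValueError("dt must be positive or 'auto'")


@dataclass
class TemperatureSeries:
    """Temperature snapshots over treatment time.

    ``fields`` is either the full grid per snapshot, shape
    (n_t, nx, ny, nz), or a recorded subset, shape (n_t, n_recorded)
    with ``mask`` marking the recorded voxels.  ``monitors`` holds
    interpolated traces at the requested monitor points.
    """

    times: np.ndarray
    fields: np.ndarray
    mask: np.ndarray | None = None
    monitors: np.ndarray | None = None
    monitor_points: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) != len(self.fields):
            raise ValueError("times and fields lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("temperature fields contain non-finite values")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        if self.mask is not None:
            return self.mask.shape
        return self.fields.shape[1:]

    def at_mask(self, query: np.ndarray) -> np.ndarray:
        """Temperatures at the voxels of a boolean mask, shape (n_t, m).

        The query mask must be a subset of the recorded voxels.
        """
        if self.mask is None:
            return self.fields[:, query]
        rec = np.flatnonzero(self.mask.ravel())
        want = np.flatnonzero(query.ravel())
        pos = np.searchsorted(rec, want)
        if pos.size and (pos.max(initial=0) >= rec.size or np.any(rec[pos] != want)):
            raise ValueError("query mask includes voxels that were not recorded")
        return self.fields[:, pos]

    def field_at(self, index: int, fill: float | None = None) -> np.ndarray:
        """Full 3-D field for one snapshot (unrecorded voxels get ``fill``)."""
        if self.mask is None:
            return self.fields[index]
        if fill is None:
            fill = float(self.meta.get("initial_temp", np.nan))
        out = np.full(self.mask.shape, fill, dtype=self.fields.dtype)
        out[self.mask] = self.fields[index]
        return out

    def to_hdf5(self, path: str) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("fields", data=self.fields)
            if self.mask is not None:
                f.create_dataset("mask", data=self.mask)
            if self.monitors is not None:
                f.create_dataset("monitors", data=self.monitors)
            f.attrs["monitor_points"] = json.dumps([list(p) for p in self.monitor_points])
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path: str) -> "TemperatureSeries":
        import h5py, json

        with h5py.File(path, "r") as f:
            return cls(
                times=f["times"][...],
                fields=f["fields"][...],
                mask=f["mask"][...] if "mask" in f else None,
                monitors=f["monitors"][...] if "monitors" in f else None,
                monitor_points=tuple(tuple(p) for p in json.loads(f.attrs["monitor_points"])),
                meta=json.loads(f.attrs["meta"]),
            )


def stable_dt(phantom, safety: float = 0.5) -> float:
    """Explicit-scheme stability bound (s) scaled by ``safety``.

    Per active voxel the bound is rho c_v / (2 k (1/dx^2 + 1/dy^2 +
    1/dz^2)) in SI units; the minimum over the phantom governs.
    """
    if not 0.0 < safety <= 1.0:
        raise ValueError("safety must lie in (0, 1]")
    act = phantom.active
    if not act.any():
        raise ValueError("phantom has no active voxels")
    k = phantom.k[act]
    rcv = phantom.rho[act] * phantom.c_v[act]
    if np.any(k <= 0) or np.any(rcv <= 0):
        raise ValueError("degenerate thermal properties")
    inv_d2 = (
        1.0 / (phantom.dx * 1e-3) ** 2
        + 1.0 / (phantom.dy * 1e-3) ** 2
        + 1.0 / (phantom.dz * 1e-3) ** 2
    )
    return safety * float(np.min(rcv / (2.0 * k * inv_d2)))


# -- stencil machinery ---------------------------------------------------


def _face_conductances(phantom):
    """Harmonic-mean face conductances (W/K) along +x, +y, +z.

    Gx[i] couples voxels i and i+1; zero across inactive voxels (grid
    edges have no array entry, hence are adiabatic by construction).
    """
    dx = phantom.dx * 1e-3
    dy = phantom.dy * 1e-3
    dz = phantom.dz * 1e-3
    k = phantom.k
    act = phantom.active

    def pair(ka, kb):
        s = ka + kb
        out = np.zeros_like(ka)
        nz_ = s > 0
        out[nz_] = 2.0 * ka[nz_] * kb[nz_] / s[nz_]
        return out

    gx = pair(k[:-1, :, :], k[1:, :, :]) * (dy * dz / dx) * (act[:-1] & act[1:])
    gy = pair(k[:, :-1, :], k[:, 1:, :]) * (dx * dz / dy) * (act[:, :-1] & act[:, 1:])
    gz = pair(k[:, :, :-1], k[:, :, 1:]) * (dx * dy / dz) * (act[:, :, :-1] & act[:, :, 1:])
    return gx, gy, gz


def _fixed_mask(phantom, boundary: str) -> np.ndarray:
    """Voxels clamped to the far-field temperature."""
    fixed = np.zeros(phantom.shape, dtype=np.bool_)
    if boundary == "adiabatic":
        return fixed
    act = phantom.active
    fixed[:, :, -1] = True  # bottom
    # lateral ring: active voxels with an inactive or out-of-grid x/y neighbor
    edge = np.zeros_like(fixed)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    inner = np.zeros_like(fixed)
    inner[1:, :, :] |= ~act[:-1, :, :]
    inner[:-1, :, :] |= ~act[1:, :, :]
    inner[:, 1:, :] |= ~act[:, :-1, :]
    inner[:, :-1, :] |= ~act[:, 1:, :]
    fixed |= edge | inner
    return fixed & act


@njit(cache=True)
def _advance(T, Tn, gx, gy, gz, inv_cap, src_rate, active, fixed, t_fixed,
             on_steps, s0, s1, dt):
    nx, ny, nz = T.shape
    for s in range(s0, s1):
        on = on_steps[s]
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not active[i, j, k]:
                        Tn[i, j, k] = T[i, j, k]
                        continue
                    if fixed[i, j, k]:
                        Tn[i, j, k] = t_fixed
                        continue
                    c = T[i, j, k]
                    acc = 0.0
                    if i > 0:
                        acc += gx[i - 1, j, k] * (T[i - 1, j, k] - c)
                    if i < nx - 1:
                        acc += gx[i, j, k] * (T[i + 1, j, k] - c)
                    if j > 0:
                        acc += gy[i, j - 1, k] * (T[i, j - 1, k] - c)
                    if j < ny - 1:
                        acc += gy[i, j, k] * (T[i, j + 1, k] - c)
                    if k > 0:
                        acc += gz[i, j, k - 1] * (T[i, j, k - 1] - c)
                    if k < nz - 1:
                        acc += gz[i, j, k] * (T[i, j, k + 1] - c)
                    d = dt * inv_cap[i, j, k] * acc
                    if on:
                        d += dt * src_rate[i, j, k]
                    Tn[i, j, k] = c + d
        tmp = T
        T = Tn
        Tn = tmp
    return T, Tn


def step(
    T: np.ndarray,
    phantom,
    absorption: AbsorptionMap | None,
    power_mw: float,
    dt: float,
    on: bool,
    boundary: str = "adiabatic",
    t_fixed: float = 37.0,
) -> np.ndarray:
    """One explicit update of the temperature field; returns a new array.

    Convenience wrapper over the compiled stepper for unit-scale use;
    ``run`` drives long integrations.
    """
    if T.shape != phantom.shape:
        raise ValueError("field shape does not match phantom")
    if dt > stable_dt(phantom, 1.0) * (1 + 1e-12):
        raise ValueError("dt exceeds the explicit stability bound")
    gx, gy, gz = _face_conductances(phantom)
    cap = phantom.rho * phantom.c_v * (phantom.voxel_volume_mm3 * 1e-9)
    inv_cap = 1.0 / cap
    if absorption is None or power_mw == 0:
        src = np.zeros(phantom.shape)
    else:
        src = absorption.a * (power_mw * 1e-3) * inv_cap
    fixed = _fixed_mask(phantom, boundary)
    on_steps = np.array([bool(on)])
    Ta = np.array(T, dtype=float)
    Tb = np.empty_like(Ta)
    out, _ = _advance(Ta, Tb, gx, gy, gz, inv_cap, src, phantom.active,
                      fixed, float(t_fixed), on_steps, 0, 1, float(dt))
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))[0]
        raise SolverDivergedError(
            f"non-finite temperature at voxel {tuple(int(b) for b in bad)}; "
            "reduce the time step"
        )
    return out


def run(
    phantom,
    absorption: AbsorptionMap | None,
    schedule: TreatmentSchedule,
    power_mw: float,
    config: SolverConfig = SolverConfig(),
    record_mask: np.ndarray | None = None,
    monitor_points: Sequence[tuple[float, float, float]] = (),
    dtype=np.float64,
) -> TemperatureSeries:
    """Integrate the bioheat equation over the full treatment.

    Returns snapshots every ``config.snapshot_interval`` seconds
    (including t = 0).  ``record_mask`` restricts the stored voxels
    (monitor traces are always interpolated from the full field).
    Deterministic: identical inputs give identical output.
    """
    snap = float(config.snapshot_interval)
    if config.dt == "auto":
        dt_max = stable_dt(phantom, config.safety)
    else:
        dt_max = float(config.dt)
        if dt_max > stable_dt(phantom, 1.0) * (1 + 1e-12):
            raise ValueError("dt exceeds the explicit stability bound")
    steps_per_snap = max(1, int(math.ceil(snap / dt_max - 1e-12)))
    dt = snap / steps_per_snap
    n_snap = int(round(schedule.tau_tot / snap))
    n_steps = n_snap * steps_per_snap
    on_steps = np.zeros(n_steps, dtype=np.bool_)
    if power_mw != 0 and absorption is not None:
        for s in range(n_steps):
            on_steps[s] = laser_on(s * dt, schedule)

    gx, gy, gz = _face_conductances(phantom)
    cap = phantom.rho * phantom.c_v * (phantom.voxel_volume_mm3 * 1e-9)
    inv_cap = 1.0 / cap
    if absorption is None or power_mw == 0:
        src = np.zeros(phantom.shape)
    else:
        src = absorption.a * (power_mw * 1e-3) * inv_cap
    fixed = _fixed_mask(phantom, config.boundary)
    t_fixed = float(config.initial_temp)

    T = np.full(phantom.shape, float(config.initial_temp))
    Tn = np.empty_like(T)

    times = np.arange(n_snap + 1) * snap
    if record_mask is not None:
        rec = np.flatnonzero(record_mask.ravel())
        fields = np.empty((n_snap + 1, rec.size), dtype=dtype)
    else:
        fields = np.empty((n_snap + 1,) + phantom.shape, dtype=dtype)
    monitors = np.empty((n_snap + 1, len(monitor_points))) if monitor_points else None

    def record(idx: int) -> None:
        if record_mask is not None:
            fields[idx] = T.ravel()[rec]
        else:
            fields[idx] = T
        if monitors is not None:
            for m, (px, py, pz) in enumerate(monitor_points):
                monitors[idx, m] = phantom.sample_field(T, px, py, pz)

    record(0)
    for sn in range(n_snap):
        T, Tn = _advance(
            T, Tn, gx, gy, gz, inv_cap, src, phantom.active, fixed, t_fixed,
            on_steps, sn * steps_per_snap, (sn + 1) * steps_per_snap, dt,
        )
        if not np.all(np.isfinite(T)):
            bad = np.argwhere(~np.isfinite(T))[0]
            raise SolverDivergedError(
                f"non-finite temperature at voxel {tuple(int(b) for b in bad)} "
                f"near t={times[sn + 1]:.3f}s; reduce the time step"
            )
        record(sn + 1)

    return TemperatureSeries(
        times=times,
        fields=fields,
        mask=None if record_mask is None else np.asarray(record_mask, dtype=bool),
        monitors=monitors,
        monitor_points=tuple(tuple(p) for p in monitor_points),
        meta={
            "dt": dt,
            "n_steps": n_steps,
            "n_on_steps": int(on_steps.sum()),
            "boundary": config.boundary,
            "initial_temp": config.initial_temp,
            "power_mw": power_mw,
            "phi_c": schedule.phi_c,
            "tau_h": schedule.tau_h,
            "tau_tot": schedule.tau_tot,
        },
    )


def export_monitor_csv(series: TemperatureSeries, path: str) -> None:
    """Write monitored-point traces as CSV (time_s, then one column per point)."""
    import pandas as pd

    if series.monitors is None:
        raise ValueError("series has no monitor traces")
    cols = {"time_s": series.times}
    names = []
    for p in series.monitor_points:
        if tuple(p) == TUMOR_MONITOR_MM:
            names.append("T_tumor_C")
        elif tuple(p) == NORMAL_MONITOR_MM:
            names.append("T_normal_C")
        else:
            names.append(f"T_at_{p[0]}_{p[1]}_{p[2]}_C")
    for m, name in enumerate(names):
        cols[name] = series.monitors[:, m]
    pd.DataFrame(cols).to_csv(path, index=False)
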