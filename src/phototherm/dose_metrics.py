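"""Thermal-dose metrics for photothermal treatment planning.

Three scalar figures of merit summarize one treatment condition:

* theta_A(t) — fraction of tumor volume inside the apoptosis band
  (43 <= T < 50 deg C); its treatment-time average is theta_A*.
  Apoptotic death is the desired mode: cells self-destruct without
  spilling content into surrounding tissue.  Above 50 deg C necrosis
  takes over, so a voxel at 50 deg C does not count as apoptotic.
* theta_H(t) — temperature-band-weighted fraction of normal-tissue
  volume, the thermal hazard; time average theta_H*.  The weighting is
  a named, versioned configuration object.  The default ("graded-v1")
  assigns small increasing weights across the hyperthermia range
  (37.5–43 deg C), weight 1 in the apoptosis band and 2 at necrotic
  temperatures, so the hazard grows smoothly with laser power the way
  thermal damage to living tissue does; a coarser scheme ("band-v1",
  nonzero only from 43 deg C up) is also provided.  Both are declared
  stand-ins for a tissue-response weighting and are swappable.
* theta_eff* = theta_A* / max(theta_H*, eps) — the optimization
  objective, rewarding tumor dose and penalizing collateral heating;
  eps guards the zero-hazard case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ApoptosisBand",
    "HazardWeighting",
    "MetricSeries",
    "DEFAULT_BAND",
    "DEFAULT_HAZARD",
    "BAND_HAZARD",
    "GRADED_HAZARD",
    "apoptosis_ratio",
    "thermal_hazard",
    "retention_average",
    "effective_ratio",
    "evaluate_series",
    "band_retention_over_powers",
]

EPS_DEFAULT = 1e-3


@dataclass(frozen=True)
class ApoptosisBand:
    """Temperature window treated as apoptotic, [lower, upper) deg C."""

    lower: float = 43.0
    upper: float = 50.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("band lower bound must be below upper bound")


@dataclass(frozen=True)
class HazardWeighting:
    """Piecewise-constant temperature weighting for normal-tissue damage.

    ``weights[i]`` applies on [breakpoints[i], breakpoints[i+1]) and the
    last weight from the last breakpoint upward; temperatures below the
    first breakpoint carry weight zero.
    """

    name: str = "band-v1"
    breakpoints: tuple[float, ...] = (43.0, 50.0)
    weights: tuple[float, ...] = (1.0, 2.0)

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) == 0 or len(bp) != len(self.weights):
            raise ValueError("need one weight per breakpoint")
        if any(b <= a for a, b in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")

    def weight_of(self, temps: np.ndarray) -> np.ndarray:
        """Weight for each temperature value."""
        w = np.concatenate([[0.0], np.asarray(self.weights, dtype=float)])
        idx = np.searchsorted(np.asarray(self.breakpoints), temps, side="right")
        return w[idx]


DEFAULT_BAND = ApoptosisBand()

#: Coarse scheme: hazard only at apoptotic/necrotic temperatures.
BAND_HAZARD = HazardWeighting("band-v1", (43.0, 50.0), (1.0, 2.0))

#: Graded scheme: mild hyperthermia (37.5-43 deg C) carries small but
#: nonzero weight, rising through the apoptosis band to necrosis.
GRADED_HAZARD = HazardWeighting(
    "graded-v1",
    (37.5, 39.0, 41.0, 43.0, 50.0),
    (0.05, 0.1, 0.3, 1.0, 2.0),
)

DEFAULT_HAZARD = GRADED_HAZARD


@dataclass
class MetricSeries:
    """theta_A(t), theta_H(t) traces and their treatment-time averages."""

    times: np.ndarray
    theta_a: np.ndarray
    theta_h: np.ndarray
    theta_a_star: float
    theta_h_star: float
    theta_eff_star: float
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.theta_a < 0) | (self.theta_a > 1)):
            raise ValueError("theta_a must lie in [0, 1]")
        if np.any(self.theta_h < 0):
            raise ValueError("theta_h must be non-negative")

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.times, "thetaA": self.theta_a, "thetaH": self.theta_h}
        ).to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "thetaA_star": self.theta_a_star,
            "thetaH_star": self.theta_h_star,
            "thetaEff_star": self.theta_eff_star,
            **self.condition,
        }


def apoptosis_ratio(field: np.ndarray, tumor_mask: np.ndarray, band: ApoptosisBand = DEFAULT_BAND) -> float:
    """Fraction of tumor volume inside the apoptosis band for one field."""
    if not np.any(tumor_mask):
        raise ValueError("tumor mask is empty")
    t = field[tumor_mask]
    return float(np.count_nonzero((t >= band.lower) & (t < band.upper)) / t.size)


def thermal_hazard(
    field: np.ndarray, normal_mask: np.ndarray, weighting: HazardWeighting = DEFAULT_HAZARD
) -> float:
    """Band-weighted mean damage indicator over normal tissue."""
    if not np.any(normal_mask):
        raise ValueError("normal mask is empty")
    t = field[normal_mask]
    return float(weighting.weight_of(t).mean())


def retention_average(times: np.ndarray, values: np.ndarray) -> float:
    """Time-weighted mean of a trace over the treatment (trapezoidal)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or v.size != t.size:
        raise ValueError("need a non-empty trace with matching times")
    if t.size == 1:
        return float(v[0])
    span = t[-1] - t[0]
    return float(np.trapezoid(v, t) / span)


def effective_ratio(theta_a_star: float, theta_h_star: float, eps: float = EPS_DEFAULT) -> float:
    """theta_eff* = theta_A* / max(theta_H*, eps)."""
    if theta_a_star < 0 or theta_h_star < 0:
        raise ValueError("retention values must be non-negative")
    return theta_a_star / max(theta_h_star, eps)


def evaluate_series(
    series,
    phantom,
    band: ApoptosisBand = DEFAULT_BAND,
    weighting: HazardWeighting = DEFAULT_HAZARD,
    eps: float = EPS_DEFAULT,
    condition: dict | None = None,
) -> MetricSeries:
    """Compute all dose metrics from a temperature series over a phantom."""
    tum = series.at_mask(phantom.tumor_mask)
    nor = series.at_mask(phantom.normal_mask)
    theta_a = np.count_nonzero((tum >= band.lower) & (tum < band.upper), axis=1) / tum.shape[1]
    theta_h = weighting.weight_of(nor).mean(axis=1)
    a_star = retention_average(series.times, theta_a)
    h_star = retention_average(series.times, theta_h)
    return MetricSeries(
        times=np.asarray(series.times, dtype=float),
        theta_a=theta_a,
        theta_h=theta_h,
        theta_a_star=a_star,
        theta_h_star=h_star,
        theta_eff_star=effective_ratio(a_star, h_star, eps),
        condition=dict(condition or {}),
    )


def band_retention_over_powers(
    times: np.ndarray,
    unit_rise: np.ndarray,
    baseline: float,
    powers: np.ndarray,
    breakpoints: tuple[float, ...],
    weights: tuple[float, ...],
) -> np.ndarray:
    """Time-averaged band-weighted volume fraction for many laser powers.

    ``unit_rise`` has shape (n_t, m): temperature rise above baseline per
    unit power for m voxels.  Because diffusion is linear in the source,
    the field at power P is ``baseline + P * unit_rise``, so one solve
    serves every power; each snapshot row is sorted once and band counts
    come from binary searches.  Temperatures below the first breakpoint
    carry weight zero (the baseline must sit below it).

    Returns the (n_powers,) array of trapezoidal time averages.
    """
    bp = np.asarray(breakpoints, dtype=float)
    w = np.asarray(weights, dtype=float)
    if baseline >= bp[0]:
        raise ValueError("baseline must lie below the first breakpoint")
    powers = np.asarray(powers, dtype=float)
    n_t, m = unit_rise.shape
    su = np.sort(np.asarray(unit_rise), axis=1)  # keep input dtype: rows can be large

    pos = powers > 0
    thr = np.empty((powers.size, bp.size))
    thr[pos] = (bp[None, :] - baseline) / powers[pos, None]
    trace = np.zeros((powers.size, n_t))
    if pos.any():
        q = thr[pos].ravel()
        n_pos = int(pos.sum())
        for ti in range(n_t):
            idx = np.searchsorted(su[ti], q).reshape(n_pos, bp.size)
            counts = np.diff(np.concatenate([idx, np.full((n_pos, 1), m)], axis=1), axis=1)
            trace[pos, ti] = counts @ w / m
    t = np.asarray(times, dtype=float)
    span = t[-1] - t[0]
    return np.trapezoid(trace, t, axis=1) / span
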