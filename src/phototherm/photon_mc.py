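"""Monte Carlo photon transport in the voxelized phantom.

Photon packets are launched uniformly over the top-hat beam disk at
normal incidence and propagated by the classic hop/drop/spin scheme:

* hop — free path ``S = -ln(xi) / mu_tot`` (the sampled dimensionless
  optical depth is walked voxel-by-voxel so heterogeneous media are
  handled without re-drawing at interfaces);
* drop — at each interaction a fraction ``mu_a / mu_tot`` of the packet
  weight is deposited in the current voxel;
* spin — azimuth ``psi = 2 pi xi`` and deflection cosine from the
  Henyey–Greenstein inverse transform with the local anisotropy ``g``.

Packets are terminated by unbiased Russian roulette (threshold 1e-4,
survival probability 0.1, survivor weight x10).  Boundaries are matched
(no Fresnel/specular physics): a packet crossing the surface, the lateral
domain limit or the bottom escapes and is tallied.  The per-voxel tally,
normalized per launched packet, is the fraction of emitted laser energy
absorbed in that voxel — the quantity the heat solver consumes.

Randomness comes from a stateless splitmix64-style counter generator
keyed on (seed, packet index, draw counter), so results are bit
reproducible for a fixed seed on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .phantom import TissuePhantom

__all__ = [
    "PhotonPacket",
    "LaserSource",
    "AbsorptionMap",
    "sample_step",
    "sample_azimuth",
    "sample_deflection",
    "update_direction",
    "deposit_weight",
    "trace",
    "downsample",
    "uniform_draws",
]

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_VERTICAL_LIMIT = 0.99999
_EPS_MM = 1e-9  # boundary nudge


# -- counter-based RNG ---------------------------------------------------

_U64 = np.uint64
_PHI64 = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + _PHI64) * _MIX1
    z ^= z >> _U64(29)
    z *= _MIX2
    z ^= z >> _U64(32)
    z *= _MIX1
    z ^= z >> _U64(29)
    return z


@njit(cache=True, inline="always")
def _xi(seed, stream, counter):
    """Uniform draw in (0, 1] for (seed, stream, counter)."""
    z = _mix64(seed ^ _mix64(stream * _PHI64))
    z = _mix64(z + counter)
    # 53-bit mantissa -> u in [0,1); return 1-u in (0,1]
    return 1.0 - (z >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _draws_kernel(seed, stream, n):
    out = np.empty(n)
    for c in range(n):
        out[c] = _xi(seed, stream, _U64(c))
    return out


def uniform_draws(seed: int, stream: int, n: int) -> np.ndarray:
    """The first ``n`` uniform (0,1] draws of one generator stream.

    Exposes the kernel's random sequence for distributional tests.
    """
    return _draws_kernel(_U64(seed), _U64(stream), int(n))


# -- domain types --------------------------------------------------------


@dataclass(frozen=True)
class PhotonPacket:
    """One photon packet: position (mm), unit direction, energy weight."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    weight: float

    def __post_init__(self) -> None:
        norm = math.sqrt(sum(c * c for c in self.direction))
        if abs(norm - 1.0) > 1e-10:
            raise ValueError("direction must be a unit vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class LaserSource:
    """Top-hat beam at normal incidence on the skin surface.

    power_mw is the emitted optical power; wavelength is metadata (all
    optical coefficients are already at the operating wavelength).
    """

    power_mw: float
    radius_mm: float = 5.0
    wavelength_nm: float = 1064.0
    profile: str = "top-hat"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("beam radius must be positive")
        if self.power_mw < 0:
            raise ValueError("power must be non-negative")


@dataclass
class AbsorptionMap:
    """Per-voxel absorbed fraction of emitted energy, plus escape tallies.

    ``a[i, j, k]`` is the fraction of launched energy absorbed in voxel
    (i, j, k); multiplying by the laser power gives the volumetric heat
    source integrated over the voxel.  ``roulette_net`` is the weight
    destroyed minus created by Russian roulette (zero mean), included in
    the conservation balance so that

        a.sum() + escape_top + escape_bottom + escape_lateral
        + roulette_net == 1           (to float round-off)
    """

    a: np.ndarray
    escape_top: float
    escape_bottom: float
    escape_lateral: float
    roulette_net: float
    n_photons: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def escaped(self) -> float:
        return self.escape_top + self.escape_bottom + self.escape_lateral

    @property
    def balance(self) -> float:
        return float(self.a.sum()) + self.escaped + self.roulette_net

    @property
    def absorbed_fraction(self) -> float:
        return float(self.a.sum())

    def to_hdf5(self, path: str) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            f.create_dataset("a", data=self.a)
            for name in ("escape_top", "escape_bottom", "escape_lateral", "roulette_net"):
                f.attrs[name] = getattr(self, name)
            f.attrs["n_photons"] = self.n_photons
            f.attrs["seed"] = self.seed
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path: str) -> "AbsorptionMap":
        import h5py, json

        with h5py.File(path, "r") as f:
            return cls(
                a=f["a"][...],
                escape_top=float(f.attrs["escape_top"]),
                escape_bottom=float(f.attrs["escape_bottom"]),
                escape_lateral=float(f.attrs["escape_lateral"]),
                roulette_net=float(f.attrs["roulette_net"]),
                n_photons=int(f.attrs["n_photons"]),
                seed=int(f.attrs["seed"]),
                meta=json.loads(f.attrs["meta"]),
            )


# -- elementary samplers (validated, array-friendly) ---------------------


def sample_step(xi, mutot: float):
    """Free path length S = -ln(xi) / mu_tot (mm)."""
    if mutot <= 0:
        raise ValueError("mutot must be positive")
    return -np.log(xi) / mutot


def sample_azimuth(xi):
    """Azimuthal scattering angle psi = 2 pi xi, uniform on [0, 2 pi)."""
    return 2.0 * np.pi * np.asarray(xi) if np.ndim(xi) else 2.0 * np.pi * xi


def sample_deflection(xi, g: float):
    """Deflection cosine: Henyey–Greenstein inverse transform.

    For g = 0 the phase function is isotropic and cos(theta) = 2 xi - 1.
    The result is clamped to [-1, 1] against round-off at extreme draws.
    """
    if not 0.0 <= g < 1.0:
        raise ValueError("anisotropy factor g must lie in [0, 1)")
    xi = np.asarray(xi, dtype=float)
    if g == 0.0:
        out = 2.0 * xi - 1.0
    else:
        term = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
        out = (1.0 + g * g - term * term) / (2.0 * g)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def update_direction(direction, cos_theta: float, psi: float) -> tuple[float, float, float]:
    """Rotate a unit direction by deflection cos(theta) and azimuth psi.

    Near-vertical directions (|mu_z| > 0.99999) use the degenerate polar
    form; otherwise the standard scattering rotation about the incoming
    direction, which preserves the unit norm exactly.
    """
    ux, uy, uz = (float(c) for c in direction)
    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
    if abs(norm - 1.0) > 1e-10:
        raise ValueError("direction must be a unit vector")
    if not -1.0 <= cos_theta <= 1.0:
        raise ValueError("cos_theta must lie in [-1, 1]")
    st = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cp, sp = math.cos(psi), math.sin(psi)
    if abs(uz) > _VERTICAL_LIMIT:
        return (st * cp, st * sp, math.copysign(cos_theta, uz))
    den = math.sqrt(1.0 - uz * uz)
    nx = st * (ux * uz * cp - uy * sp) / den + ux * cos_theta
    ny = st * (uy * uz * cp + ux * sp) / den + uy * cos_theta
    nz = -st * cp * den + uz * cos_theta
    return (nx, ny, nz)


def deposit_weight(packet: PhotonPacket, mua: float, mutot: float) -> tuple[float, PhotonPacket]:
    """Interaction deposit: dW = W mu_a / mu_tot; returns (dW, updated packet)."""
    if mutot <= 0:
        raise ValueError("mutot must be positive")
    if mua < 0 or mua > mutot:
        raise ValueError("need 0 <= mua <= mutot")
    dw = packet.weight * mua / mutot
    new = PhotonPacket(packet.position, packet.direction, packet.weight - dw)
    return dw, new


# -- transport kernel ----------------------------------------------------


@njit(cache=True)
def _trace_kernel(mua, mus, g, active, dx, dy, dz, x0, y0,
                  beam_r, specular, n_photons, seed):
    nx, ny, nz = mua.shape
    zmax = nz * dz
    acc = np.zeros((nx, ny, nz))
    esc_top = 0.0
    esc_bottom = 0.0
    esc_lateral = 0.0
    roulette_net = 0.0
    seed_u = _U64(seed)
    two_pi = 2.0 * np.pi

    for p in range(n_photons):
        stream = _U64(p + 1)
        ctr = _U64(0)
        # launch: uniform over the beam disk, straight down
        xi1 = _xi(seed_u, stream, ctr); ctr += _U64(1)
        xi2 = _xi(seed_u, stream, ctr); ctr += _U64(1)
        rr = beam_r * math.sqrt(xi1)
        phi = two_pi * xi2
        x = rr * math.cos(phi)
        y = rr * math.sin(phi)
        z = 1e-12
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        if specular > 0.0:
            esc_top += specular
            w -= specular

        xi = _xi(seed_u, stream, ctr); ctr += _U64(1)
        tau = -math.log(xi)  # remaining dimensionless optical depth

        for _hop in range(10_000_000):
            i = int(math.floor((x - x0) / dx))
            j = int(math.floor((y - y0) / dy))
            k = int(math.floor(z / dz))
            if k < 0:
                esc_top += w
                w = -1.0
                break
            if k >= nz:
                esc_bottom += w
                w = -1.0
                break
            if i < 0 or i >= nx or j < 0 or j >= ny or not active[i, j, k]:
                esc_lateral += w
                w = -1.0
                break

            mt = mua[i, j, k] + mus[i, j, k]
            # distance to the voxel boundary along the direction of flight
            tb = 1e30
            if ux > 0.0:
                t = (x0 + (i + 1) * dx - x) / ux
                if t < tb:
                    tb = t
            elif ux < 0.0:
                t = (x0 + i * dx - x) / ux
                if t < tb:
                    tb = t
            if uy > 0.0:
                t = (y0 + (j + 1) * dy - y) / uy
                if t < tb:
                    tb = t
            elif uy < 0.0:
                t = (y0 + j * dy - y) / uy
                if t < tb:
                    tb = t
            if uz > 0.0:
                t = ((k + 1) * dz - z) / uz
                if t < tb:
                    tb = t
            elif uz < 0.0:
                t = (k * dz - z) / uz
                if t < tb:
                    tb = t
            if tb < 0.0:
                tb = 0.0

            if mt <= 0.0 or mt * tb < tau:
                # cross into the next voxel, consuming optical depth
                if mt > 0.0:
                    tau -= mt * tb
                step = tb + _EPS_MM
                x += step * ux
                y += step * uy
                z += step * uz
                continue

            # interaction inside this voxel
            s = tau / mt
            x += s * ux
            y += s * uy
            z += s * uz
            dw = w * mua[i, j, k] / mt
            acc[i, j, k] += dw
            w -= dw

            if w < ROULETTE_THRESHOLD:
                xi = _xi(seed_u, stream, ctr); ctr += _U64(1)
                if xi <= ROULETTE_SURVIVAL:
                    roulette_net -= w * (1.0 / ROULETTE_SURVIVAL - 1.0)
                    w *= 1.0 / ROULETTE_SURVIVAL
                else:
                    roulette_net += w
                    w = -1.0
                    break

            # spin
            xi = _xi(seed_u, stream, ctr); ctr += _U64(1)
            psi = two_pi * xi
            gg = g[i, j, k]
            xi = _xi(seed_u, stream, ctr); ctr += _U64(1)
            if gg == 0.0:
                ct = 2.0 * xi - 1.0
            else:
                term = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi)
                ct = (1.0 + gg * gg - term * term) / (2.0 * gg)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            cp = math.cos(psi)
            sp = math.sin(psi)
            if abs(uz) > _VERTICAL_LIMIT:
                ux2 = st * cp
                uy2 = st * sp
                uz2 = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux2 = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy2 = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz2 = -st * cp * den + uz * ct
            inv = 1.0 / math.sqrt(ux2 * ux2 + uy2 * uy2 + uz2 * uz2)
            ux = ux2 * inv
            uy = uy2 * inv
            uz = uz2 * inv

            xi = _xi(seed_u, stream, ctr); ctr += _U64(1)
            tau = -math.log(xi)

        if w >= 0.0:
            # hop cap reached (pathological phantom); count as lateral loss
            esc_lateral += w

    return acc, esc_top, esc_bottom, esc_lateral, roulette_net


def downsample(amap: AbsorptionMap, factor: int) -> AbsorptionMap:
    """Block-sum an absorption map onto a coarser grid.

    Light transport must resolve the 0.08 mm epidermis (its scattering
    controls how much of the beam is backscattered before reaching the
    tumor), but the explicit heat solver cannot afford such voxels.  The
    absorbed fraction is an extensive quantity, so summing fine voxels
    into ``factor``-cubed blocks conserves energy exactly and yields the
    source map for a coarser thermal grid.
    """
    f = int(factor)
    if f < 1 or f != factor:
        raise ValueError("factor must be a positive integer")
    nx, ny, nz = amap.a.shape
    if nx % f or ny % f or nz % f:
        raise ValueError("grid dimensions are not divisible by factor")
    a = amap.a.reshape(nx // f, f, ny // f, f, nz // f, f).sum(axis=(1, 3, 5))
    out = AbsorptionMap(
        a=a,
        escape_top=amap.escape_top,
        escape_bottom=amap.escape_bottom,
        escape_lateral=amap.escape_lateral,
        roulette_net=amap.roulette_net,
        n_photons=amap.n_photons,
        seed=amap.seed,
        meta=dict(amap.meta),
    )
    out.meta["downsample_factor"] = f * out.meta.get("downsample_factor", 1)
    return out


def trace(
    phantom: TissuePhantom,
    source: LaserSource,
    n_photons: int = 100_000,
    seed: int = 0,
    specular_fraction: float = 0.0,
) -> AbsorptionMap:
    """Run the transport simulation and return the normalized absorption map.

    Parameters
    ----------
    phantom:
        Voxel phantom providing per-voxel mu_a, mu_s, g and the active mask.
    source:
        Beam geometry; only the radius matters here (the map is per unit
        emitted power — scale by ``power_mw`` downstream).
    n_photons:
        Number of packets.  1e5 is adequate for tests; 1e6 for production.
    seed:
        Any Python int; identical seeds give bit-identical maps.
    specular_fraction:
        Optional fraction of incident energy reflected at the surface
        before entering the tissue (default 0: matched boundary).
    """
    if not isinstance(n_photons, (int, np.integer)) or n_photons < 1:
        raise ValueError("n_photons must be a positive integer")
    if not isinstance(seed, (int, np.integer)):
        raise ValueError("seed must be an integer")
    if not 0.0 <= specular_fraction < 1.0:
        raise ValueError("specular_fraction must lie in [0, 1)")

    acc, et, eb, el, rn = _trace_kernel(
        phantom.mua,
        phantom.mus,
        phantom.g,
        phantom.active,
        phantom.dx,
        phantom.dy,
        phantom.dz,
        phantom.x0,
        phantom.y0,
        source.radius_mm,
        specular_fraction,
        int(n_photons),
        int(seed) & 0x7FFFFFFFFFFFFFFF,
    )
    n = float(n_photons)
    return AbsorptionMap(
        a=acc / n,
        escape_top=et / n,
        escape_bottom=eb / n,
        escape_lateral=el / n,
        roulette_net=rn / n,
        n_photons=int(n_photons),
        seed=int(seed),
        meta={
            "beam_radius_mm": source.radius_mm,
            "specular_fraction": specular_fraction,
            "fv_label": phantom.meta.get("fv_label"),
            "voxel_size": phantom.meta.get("voxel_size"),
        },
    )
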