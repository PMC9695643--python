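"""Voxelized four-layer skin phantom with an embedded tumor.

The treatment-planning domain is a cylinder of radius 15 mm and depth
20 mm of layered skin (epidermis, papillary dermis, reticular dermis,
subcutaneous fat) containing a squamous-cell-carcinoma cylinder of radius
5 mm and depth 2 mm whose top face sits 0.1 mm below the surface, on the
beam axis.  The cylinder is voxelized on a Cartesian grid (the heat
solver stencil is Cartesian); voxels whose centers fall outside the
15 mm radius are marked inactive.

Coordinate convention: z increases downward from the skin surface, the
origin is on the beam axis at the surface, voxel (i, j, k) owns the
half-open box [i*d, (i+1)*d) per axis, and x/y are centered on the axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .gnp_optics import TUMOR_BASE, tumor_optics_for_fv

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "TissuePhantom",
    "SyntheticFieldSpec",
    "SKIN_LAYERS",
    "TUMOR_LAYER",
    "build_phantom",
    "homogeneous_phantom",
    "synth_temperature_series",
    "layers_from_csv",
    "DOMAIN_RADIUS_MM",
    "DOMAIN_DEPTH_MM",
    "TUMOR_RADIUS_MM",
    "TUMOR_DEPTH_MM",
    "TUMOR_TOP_MM",
]

DOMAIN_RADIUS_MM = 15.0
DOMAIN_DEPTH_MM = 20.0
TUMOR_RADIUS_MM = 5.0
TUMOR_DEPTH_MM = 2.0
TUMOR_TOP_MM = 0.1


@dataclass(frozen=True)
class LayerSpec:
    """Thermo-optical description of one tissue layer.

    thickness in mm; c_v in J/(kg K); rho in kg/m^3; k in W/(m K);
    g dimensionless in [0, 1); mua, mus in 1/mm.
    """

    name: str
    thickness: float
    c_v: float
    rho: float
    k: float
    g: float
    mua: float
    mus: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if min(self.rho, self.c_v, self.k) <= 0:
            raise ValueError("rho, c_v, k must be positive")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("g must lie in [0, 1)")
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be non-negative")


#: The four skin layers, surface first.
SKIN_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("epidermis", 0.08, 3589.0, 1200.0, 0.235, 0.8, 0.4, 45.0),
    LayerSpec("papillary dermis", 0.5, 3300.0, 1200.0, 0.445, 0.9, 0.38, 30.0),
    LayerSpec("reticular dermis", 0.6, 3300.0, 1200.0, 0.445, 0.8, 0.48, 25.0),
    LayerSpec("subcutaneous fat", 18.82, 2500.0, 1000.0, 0.19, 0.75, 0.43, 5.0),
)

#: Unloaded tumor tissue; thermal properties always come from this row.
TUMOR_LAYER = LayerSpec(
    "tumor", TUMOR_DEPTH_MM, 3421.0, 1070.0, 0.495, TUMOR_BASE[2], TUMOR_BASE[0], TUMOR_BASE[1]
)

TUMOR_REGION = len(SKIN_LAYERS)  # region code of tumor voxels
INACTIVE_REGION = -1


@dataclass
class TissuePhantom:
    """Voxel grid with per-voxel region identity and material properties.

    All property arrays have shape ``(nx, ny, nz)``.  ``region`` holds the
    layer index (0..3 skin layers surface-down, 4 tumor, -1 inactive
    outside the cylindrical domain).  Optical coefficients are in 1/mm,
    thermal properties in SI.
    """

    dx: float
    dy: float
    dz: float
    region: np.ndarray
    mua: np.ndarray
    mus: np.ndarray
    g: np.ndarray
    rho: np.ndarray
    c_v: np.ndarray
    k: np.ndarray
    x0: float  # x coordinate (mm) of the low face of voxel i=0
    y0: float
    region_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(l.name for l in SKIN_LAYERS) + ("tumor",)
    )
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.region.shape

    @property
    def active(self) -> np.ndarray:
        return self.region >= 0

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.region == TUMOR_REGION

    @property
    def normal_mask(self) -> np.ndarray:
        return self.active & ~self.tumor_mask

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) along each axis."""
        nx, ny, nz = self.shape
        cx = self.x0 + (np.arange(nx) + 0.5) * self.dx
        cy = self.y0 + (np.arange(ny) + 0.5) * self.dy
        cz = (np.arange(nz) + 0.5) * self.dz
        return cx, cy, cz

    def voxel_index(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        """Voxel containing the point (mm), clipped to the grid."""
        nx, ny, nz = self.shape
        i = min(max(int(np.floor((x - self.x0) / self.dx)), 0), nx - 1)
        j = min(max(int(np.floor((y - self.y0) / self.dy)), 0), ny - 1)
        k = min(max(int(np.floor(z / self.dz)), 0), nz - 1)
        return i, j, k

    def sample_field(self, fld: np.ndarray, x: float, y: float, z: float) -> float:
        """Trilinear interpolation of a voxel field at a point (mm).

        Values are taken at voxel centers and clamped at the grid edges,
        so points above the first center plane read the surface voxel.
        """
        nx, ny, nz = self.shape

        def axis(coord: float, origin: float, d: float, n: int) -> tuple[int, int, float]:
            u = (coord - origin) / d - 0.5
            i0 = int(np.floor(u))
            frac = u - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            return i0c, i1c, frac

        i0, i1, fx = axis(x, self.x0, self.dx, nx)
        j0, j1, fy = axis(y, self.y0, self.dy, ny)
        k0, k1, fz = axis(z, 0.0, self.dz, nz)
        fx = min(max(fx, 0.0), 1.0)
        fy = min(max(fy, 0.0), 1.0)
        fz = min(max(fz, 0.0), 1.0)
        out = 0.0
        for ii, wx in ((i0, 1 - fx), (i1, fx)):
            for jj, wy in ((j0, 1 - fy), (j1, fy)):
                for kk, wz in ((k0, 1 - fz), (k1, fz)):
                    out += wx * wy * wz * float(fld[ii, jj, kk])
        return out

    # -- persistence ----------------------------------------------------

    def to_hdf5(self, path: str) -> None:
        """Write the phantom to an HDF5 container plus a JSON layer sidecar."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dx"] = self.dx
            f.attrs["dy"] = self.dy
            f.attrs["dz"] = self.dz
            f.attrs["x0"] = self.x0
            f.attrs["y0"] = self.y0
            f.attrs["region_names"] = json.dumps(list(self.region_names))
            f.attrs["meta"] = json.dumps(self.meta)
            for name in ("region", "mua", "mus", "g", "rho", "c_v", "k"):
                f.create_dataset(name, data=getattr(self, name))
        side = {
            "layers": [
                {k2: getattr(l, k2) for k2 in ("name", "thickness", "c_v", "rho", "k", "g", "mua", "mus")}
                for l in SKIN_LAYERS + (TUMOR_LAYER,)
            ]
        }
        with open(str(path) + ".layers.json", "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def from_hdf5(cls, path: str) -> "TissuePhantom":
        import h5py

        with h5py.File(path, "r") as f:
            arrays = {n: f[n][...] for n in ("region", "mua", "mus", "g", "rho", "c_v", "k")}
            return cls(
                dx=float(f.attrs["dx"]),
                dy=float(f.attrs["dy"]),
                dz=float(f.attrs["dz"]),
                x0=float(f.attrs["x0"]),
                y0=float(f.attrs["y0"]),
                region_names=tuple(json.loads(f.attrs["region_names"])),
                meta=json.loads(f.attrs["meta"]),
                **arrays,
            )


def _layer_boundaries(layers=SKIN_LAYERS) -> np.ndarray:
    return np.cumsum([l.thickness for l in layers])


def build_phantom(
    voxel_size: float = 0.5,
    fv_label: float | None = 1e-6,
    blend_surface: bool = False,
) -> TissuePhantom:
    """Voxelize the layered-skin + tumor domain.

    Parameters
    ----------
    voxel_size:
        Cubic voxel edge in mm.  Must tile the 30 x 30 x 20 mm bounding
        box to within one voxel.
    fv_label:
        Nanoparticle volume fraction of the tumor; one of the published
        loadings (1e-3 .. 1e-6), any other positive value (dilute linear
        model), or ``None`` for the unloaded tumor.  Tumor thermal
        properties are independent of loading.
    blend_surface:
        If True, the surface voxel row receives thickness-weighted
        optical and volume-weighted thermal properties of the layers it
        spans (the 0.08 mm epidermis is thinner than practical voxels);
        if False (default) every voxel takes the layer containing its
        center.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    d = float(voxel_size)
    nx = int(round(2 * DOMAIN_RADIUS_MM / d))
    nz = int(round(DOMAIN_DEPTH_MM / d))
    if abs(nx * d - 2 * DOMAIN_RADIUS_MM) > d or abs(nz * d - DOMAIN_DEPTH_MM) > d or nx < 2 or nz < 2:
        raise ValueError("voxel_size must divide the domain extents to within one voxel")
    if d > SKIN_LAYERS[0].thickness:
        logger.warning(
            "voxel size %.3g mm exceeds the %.3g mm epidermis thickness; "
            "the epidermis is sub-voxel (enable blend_surface to blend "
            "surface-voxel properties)",
            d,
            SKIN_LAYERS[0].thickness,
        )
    ny = nx
    x0 = -nx * d / 2.0
    y0 = -ny * d / 2.0

    cx = x0 + (np.arange(nx) + 0.5) * d
    cz = (np.arange(nz) + 0.5) * d
    r2 = cx[:, None] ** 2 + cx[None, :] ** 2  # (nx, ny), y grid == x grid

    bounds = _layer_boundaries()
    layer_of_z = np.searchsorted(bounds, cz, side="right")
    layer_of_z = np.clip(layer_of_z, 0, len(SKIN_LAYERS) - 1)

    region = np.broadcast_to(layer_of_z[None, None, :].astype(np.int8), (nx, ny, nz)).copy()
    in_tumor_z = (cz >= TUMOR_TOP_MM) & (cz < TUMOR_TOP_MM + TUMOR_DEPTH_MM)
    in_tumor_xy = r2 < TUMOR_RADIUS_MM**2
    tumor = in_tumor_xy[:, :, None] & in_tumor_z[None, None, :]
    region[tumor] = TUMOR_REGION
    region[(r2 > DOMAIN_RADIUS_MM**2)[:, :, None] & np.ones(nz, bool)[None, None, :]] = INACTIVE_REGION

    tumor_opt = tumor_optics_for_fv(fv_label)
    specs = list(SKIN_LAYERS) + [
        LayerSpec(
            "tumor",
            TUMOR_DEPTH_MM,
            TUMOR_LAYER.c_v,
            TUMOR_LAYER.rho,
            TUMOR_LAYER.k,
            tumor_opt.g,
            tumor_opt.mua,
            tumor_opt.mus,
        )
    ]
    prop = {n: np.empty((nx, ny, nz)) for n in ("mua", "mus", "g", "rho", "c_v", "k")}
    lookup = region.copy()
    lookup[lookup < 0] = len(SKIN_LAYERS) - 1  # inactive voxels: fat properties (unused)
    for name in prop:
        table = np.array([getattr(s, name) for s in specs])
        prop[name][...] = table[lookup]

    if blend_surface:
        _blend_surface_row(prop, region, specs, d)

    ph = TissuePhantom(
        dx=d,
        dy=d,
        dz=d,
        region=region,
        x0=x0,
        y0=y0,
        meta={"fv_label": fv_label, "voxel_size": d, "blend_surface": blend_surface},
        **prop,
    )
    return ph


def _blend_surface_row(prop, region, specs, d) -> None:
    """Blend properties of the k=0 voxel row over the layers it spans.

    Optical coefficients are thickness-weighted; thermal properties are
    volume-weighted (equivalent here, the voxel cross-section is uniform).
    Tumor columns include the tumor segment starting at its top face.
    """
    bounds = np.concatenate([[0.0], _layer_boundaries()])
    nx, ny = region.shape[:2]
    is_tumor_col = region[:, :, :]  # tumor may start in row 0 or 1
    for name in prop:
        vals = np.array([getattr(s, name) for s in specs])
        # segments of [0, d) per column type
        def blended(tumor_col: bool) -> float:
            segs = []
            z = 0.0
            for li in range(len(specs) - 1):
                lo, hi = bounds[li], bounds[li + 1]
                a, b = max(lo, 0.0), min(hi, d)
                if b > a:
                    segs.append((li, a, b))
            total = 0.0
            for li, a, b in segs:
                w = b - a
                if tumor_col:
                    # carve out the tumor interval [0.1, 0.1+2) mm
                    t0, t1 = TUMOR_TOP_MM, TUMOR_TOP_MM + TUMOR_DEPTH_MM
                    ov = max(0.0, min(b, min(t1, d)) - max(a, t0))
                    w -= ov
                    total += ov * vals[-1]
                total += w * vals[li]
            return total / d
        v_norm = blended(False)
        v_tum = blended(True)
        col_has_tumor = (region == len(specs) - 1).any(axis=2)
        row = prop[name][:, :, 0]
        row[...] = np.where(col_has_tumor, v_tum, v_norm)


def homogeneous_phantom(
    n: tuple[int, int, int],
    voxel_size: float,
    mua: float,
    mus: float,
    g: float,
    rho: float = 1000.0,
    c_v: float = 4000.0,
    k: float = 0.5,
) -> TissuePhantom:
    """Uniform single-material block, for verification against closed forms.

    The whole block is labelled "tumor" so metric code treats it as one
    region; all voxels are active.
    """
    nx, ny, nz = n
    shape = (nx, ny, nz)
    full = lambda v: np.full(shape, float(v))
    return TissuePhantom(
        dx=voxel_size,
        dy=voxel_size,
        dz=voxel_size,
        region=np.full(shape, TUMOR_REGION, dtype=np.int8),
        mua=full(mua),
        mus=full(mus),
        g=full(g),
        rho=full(rho),
        c_v=full(c_v),
        k=full(k),
        x0=-nx * voxel_size / 2.0,
        y0=-ny * voxel_size / 2.0,
        meta={"homogeneous": True},
    )


# -- synthetic temperature fields for metric verification ----------------


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Parametric hot-spot field: baseline plus a spherical plateau.

    ``profile`` is a list of (time_s, amplitude_scale) pairs; at each time
    the field equals ``baseline + scale * (peak - baseline)`` inside the
    sphere of ``radius_mm`` around ``center_mm`` and ``baseline`` outside.
    Sharp edges make every dose metric exactly countable by hand.
    """

    peak: float
    baseline: float
    center_mm: tuple[float, float, float]
    radius_mm: float
    profile: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.baseline > self.peak:
            raise ValueError("baseline must not exceed peak")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        times = [t for t, _ in self.profile]
        if not times:
            raise ValueError("profile must contain at least one sample")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("profile times must be strictly increasing")


def synth_temperature_series(spec: SyntheticFieldSpec, phantom: TissuePhantom):
    """Deterministic temperature series from a synthetic hot-spot spec."""
    from .bioheat import TemperatureSeries

    cx, cy, cz = phantom.centers()
    x0, y0, z0 = spec.center_mm
    inside = (
        (cx[:, None, None] - x0) ** 2
        + (cy[None, :, None] - y0) ** 2
        + (cz[None, None, :] - z0) ** 2
    ) <= spec.radius_mm**2
    times = np.array([t for t, _ in spec.profile], dtype=float)
    fields = np.empty((len(times),) + phantom.shape)
    for i, (_, scale) in enumerate(spec.profile):
        f = np.full(phantom.shape, spec.baseline, dtype=float)
        f[inside] = spec.baseline + scale * (spec.peak - spec.baseline)
        fields[i] = f
    return TemperatureSeries(times=times, fields=fields, meta={"synthetic": True})


def layers_from_csv(path: str) -> tuple[LayerSpec, ...]:
    """Load layer specs from a CSV with the standard property columns.

    Expected columns: name, t_mm, c_v, rho, k, g, mua, mus.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["name", "t_mm", "c_v", "rho", "k", "g", "mua", "mus"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return tuple(
        LayerSpec(
            str(r["name"]), float(r["t_mm"]), float(r["c_v"]), float(r["rho"]),
            float(r["k"]), float(r["g"]), float(r["mua"]), float(r["mus"]),
        )
        for _, r in df.iterrows()
    )
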