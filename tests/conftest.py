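"""Shared fixtures: phantoms and cached Monte Carlo maps."""

import numpy as np
import pytest

from phototherm import phantom as pm
from phototherm import photon_mc as mc


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default 1 mm phantom with the lightest nanorod loading."""
    return pm.build_phantom(1.0, fv_label=1e-6)


@pytest.fixture(scope="session")
def coarse_map(coarse_phantom):
    """A 1e5-photon absorption map on the coarse phantom."""
    return mc.trace(coarse_phantom, mc.LaserSource(power_mw=1.0), n_photons=100_000, seed=7)


@pytest.fixture(scope="session")
def slab_phantom():
    """Absorbing-only homogeneous slab (mu_a = 1/mm, no scattering)."""
    return pm.homogeneous_phantom((24, 24, 12), voxel_size=0.5, mua=1.0, mus=0.0, g=0.0)


def gaussian_blob_map(phantom, total=0.8, sigma_mm=1.0):
    """Synthetic absorption map: normalized Gaussian blob at the domain center."""
    cx, cy, cz = phantom.centers()
    x0, y0, z0 = cx.mean(), cy.mean(), cz.mean()
    r2 = (
        (cx[:, None, None] - x0) ** 2
        + (cy[None, :, None] - y0) ** 2
        + (cz[None, None, :] - z0) ** 2
    )
    a = np.exp(-r2 / (2 * sigma_mm**2))
    a *= total / a.sum()
    return mc.AbsorptionMap(
        a=a, escape_top=1 - total, escape_bottom=0.0, escape_lateral=0.0,
        roulette_net=0.0, n_photons=1, seed=0, meta={"synthetic": True},
    )
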