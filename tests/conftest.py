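"""Shared fixtures: small phantoms rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from octskin.phantom import PhantomSpec, make_plate_phantom, render_volume


@pytest.fixture(scope="session")
def flat_noiseless():
    """Flat noise-free phantom: every stage should recover it exactly."""
    spec = PhantomSpec(n_slices=3, n_depth=160, n_lateral=128,
                       surface_profile="flat", amplitude=0.0, speckle="none")
    return render_volume(spec)


@pytest.fixture(scope="session")
def plate_noiseless():
    """Noise-free triangle plate with grid-exact Ra = 6.3 um."""
    spec = PhantomSpec(n_slices=3, n_depth=256, n_lateral=512, speckle="none")
    return make_plate_phantom(6.3, spec)


@pytest.fixture(scope="session")
def plate_speckled():
    """Speckled, curved 6.3 um plate at reduced slice count (fast fixture)."""
    spec = PhantomSpec(n_slices=30, n_depth=256, n_lateral=512,
                       curvature_coeff=2e-6, seed=1)
    return make_plate_phantom(6.3, spec)


@pytest.fixture(scope="session")
def skin_speckled():
    """Skin-like speckled phantom with known layer parameters."""
    spec = PhantomSpec(n_slices=20, n_depth=320, n_lateral=256,
                       surface_profile="filtered-noise", amplitude=10.0,
                       epidermis_thickness=100.0, attenuation_mu=2.0,
                       curvature_coeff=1e-6, seed=4)
    return render_volume(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
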