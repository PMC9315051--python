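"""Shared fixtures: frozen scenarios and small analytic setups."""

import numpy as np
import pytest

import pushpulse as pp

#: frozen reference seed for the end-to-end scenario fixtures
SCENARIO_SEED = 2


@pytest.fixture(scope="session")
def scenario2d():
    return pp.paper_2d_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario3d():
    return pp.paper_3d_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def gauss_wave():
    return pp.make_gaussian_subpulse(tbp=2.27, tau=4e-3, dt=10e-6)


@pytest.fixture(scope="session")
def wm_tissue():
    return pp.white_matter()


@pytest.fixture()
def uniform_single_channel_setup():
    """One channel, spatially uniform unit sensitivity (uT/V)."""
    mask = np.ones((4, 4), dtype=bool)
    return pp.TransmitSetup(
        sensitivities=np.ones((1, 4, 4), dtype=complex),
        mask=mask,
        voxel_size_mm=(10.0, 10.0),
    )


@pytest.fixture()
def complementary_two_channel_setup():
    """Two channels with |s1|^2 + |s2|^2 constant but phase twisting.

    A two-sub-pulse design driving one channel per sub-pulse delivers an
    exactly flat intensity; no single-sub-pulse combination can, because
    the relative phase twists along the profile.  Used to pin the
    CP >= PUSH-1 > PUSH-2 ordering against a grid-enumeration oracle.
    """
    n = 8
    theta = np.linspace(0.25, 1.30, n)
    phi = np.linspace(0.0, np.pi, n)
    s1 = np.cos(theta).astype(complex)
    s2 = np.sin(theta) * np.exp(1j * phi)
    sens = np.stack([s1, s2])[:, None, :]  # grid (1, n)
    return pp.TransmitSetup(
        sensitivities=sens,
        mask=np.ones((1, n), dtype=bool),
        voxel_size_mm=(10.0, 10.0),
    )


@pytest.fixture()
def generous_limits():
    return pp.HardwareLimits(v_max=1e5, p_max=1e7, impedance=50.0)


@pytest.fixture()
def identity_vops():
    """Single identity VOP: SAR equals duty * total drive power per V^2."""

    def make(n_channels, sar_limit=1e9):
        return pp.VOPSet(
            matrices=np.eye(n_channels, dtype=complex)[None, :, :],
            sar_limit=sar_limit,
        )

    return make
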