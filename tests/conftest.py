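import numpy as np
import pytest
from hypothesis import settings

import stenosim as st

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

OMEGA0 = 3.0 * np.pi  # fundamental angular frequency, 2*pi / (2/3 s)


@pytest.fixture(scope="session")
def geom():
    """Reference carotid geometry: 25% stenosis, wall at twice the fundamental."""
    return st.VesselGeometry(
        R0=4e-3, delta=1e-3, alpha=0.05, omega_wall=2 * OMEGA0,
        x0=40e-3, h=0.3e-3,
    )


@pytest.fixture(scope="session")
def straight_geom():
    return st.VesselGeometry(
        R0=4e-3, delta=0.0, alpha=0.0, omega_wall=0.0, x0=40e-3, h=0.3e-3,
    )


@pytest.fixture(scope="session")
def wall():
    return st.WallProperties(E=978e3, sigma=0.5)


@pytest.fixture(scope="session")
def fluid():
    return st.FluidProperties(rho=1050.0, mu=3.5e-3)


@pytest.fixture(scope="session")
def waveform():
    _, u = st.synth_cca_waveform(2.0 / 3.0, peak=0.8)
    return st.fourier_decompose(u, 14, tp=2.0 / 3.0)


@pytest.fixture(scope="session")
def solution(geom, wall, fluid, waveform):
    return st.solve_pulsatile(geom, wall, fluid, waveform, t_phase=0.1)
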