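import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import braincool as bc

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tissue():
    return bc.TissueProperties()


@pytest.fixture(scope="session")
def blood():
    return bc.BloodProperties()


@pytest.fixture(scope="session")
def small_domain():
    """Compact axisymmetric domain for fast solver tests.

    At 136 s the cooled front extends ~11 mm, so a 40 mm radius behaves like
    the full region of interest while solving in about a second.
    """
    return bc.SimulationDomain(height=80.0, radius=40.0)


@pytest.fixture(scope="session")
def small_cooling_fields(small_domain):
    """Transient cooling snapshots with the standard 15 degC probe."""
    solver = bc.PennesSolver(small_domain, bc.ProbeSpec(),
                             options=bc.SolverOptions(dt_max=5.0))
    return solver.solve_transient([30.0, 60.0, 136.0])


def radial_phantom_field(amplitude=5.0, scale=15.0, r_max=60.0):
    """Probe-free axisymmetric field with a smooth radial cold spot:
    T(r) = 37 - amplitude * exp(-r^2 / (2 scale^2)), uniform in z."""
    r = np.arange(0.0, r_max + 1e-9, 0.5)
    z = np.arange(-30.0, 30.0 + 1e-9, 1.0)
    T = 37.0 - amplitude * np.exp(-(r ** 2) / (2 * scale ** 2))
    return bc.ThermalField(mode="axisymmetric", axes=(r, z),
                           temperature=np.tile(T[:, None], (1, len(z))),
                           time=100.0)


@pytest.fixture()
def phantom_field():
    return radial_phantom_field()
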