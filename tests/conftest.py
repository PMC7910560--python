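import numpy as np
import pytest

import cavikin as ck
from cavikin.fixtures import table1_stationary_points


@pytest.fixture(scope="session")
def quartic_spec():
    """Generic quartic double well with a linear dipole (light mass, so the
    well spacing and frequencies are O(1) in a.u.)."""
    return ck.QuarticFixtureSpec(Eb=0.02, omega_b=0.004,
                                 mass=ck.units.PROTON_MASS_AU, mu_slope=-1.5)


@pytest.fixture(scope="session")
def quartic_model(quartic_spec):
    return quartic_spec.to_model()


@pytest.fixture(scope="session")
def ref_model():
    """Quartic surrogate of the reference proton-transfer system."""
    return ck.table1_model()


@pytest.fixture(scope="session")
def ref_sp():
    """Reference stationary-point scalars (well/barrier frequencies and
    dipole slopes of the calibrated proton-transfer model)."""
    return table1_stationary_points()


@pytest.fixture(scope="session")
def ref_model_sp(ref_model):
    return ck.stationary_points(ref_model)


@pytest.fixture(scope="session")
def sm_params():
    """Small, fast Shin-Metiu parameter set for solver tests."""
    return ck.SMParams(electron_grid=(-17.0, 17.0, 201),
                       R_grid=(-3.6, 3.6, 65))


@pytest.fixture(scope="session")
def harmonic_model():
    """Harmonic well + linear dipole: the bilinear-oscillator fixture."""
    return ck.make_harmonic_model(0.01, 1836.0, 0.5, n_sigma=10, n_points=64)


def kappa_kramers(omega_b: float, gamma: float) -> float:
    """1D Markovian (Kramers) transmission coefficient, closed form."""
    lam = -gamma / 2.0 + np.sqrt(gamma**2 / 4.0 + omega_b**2)
    return lam / omega_b
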