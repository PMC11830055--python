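import numpy as np
import pytest

from dkrfiber import BulkState, DimensionlessParameters


@pytest.fixture(scope="session")
def p_weak_diffusion():
    """Weak-diffusion reference set (profile table 4/5 base, B0 = 8.68)."""
    return DimensionlessParameters(
        phi2=0.5, b0=8.68, theta=3.27, gamma=1.0, xi1=2.0, xi2=0.03, phi_frac=1.0
    )


@pytest.fixture(scope="session")
def p_strong_diffusion():
    """Strong-diffusion reference set (profile table 6/7, Phi^2 = 10)."""
    return DimensionlessParameters(
        phi2=10.0, b0=17.34, theta=5.0, gamma=10.0, xi1=7.23, xi2=0.25, phi_frac=1.0
    )


@pytest.fixture(scope="session")
def p_mief_base():
    """Effectiveness-table base set (B0 = 8.68, Theta = 5)."""
    return DimensionlessParameters(
        phi2=1.0, b0=8.68, theta=5.0, gamma=0.0, xi1=7.23, xi2=0.25, phi_frac=1.0
    )


@pytest.fixture(scope="session")
def racemic_bulk():
    return BulkState(s1b=1.0, s2b=1.0, x_conv=0.0)


@pytest.fixture(scope="session")
def x_grid():
    return np.round(np.arange(1.0, 2.01, 0.2), 10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_parameter_sets(rng, n):
    """Random physically plausible dimensionless parameter sets, away from
    the B0 = 2 singularity."""
    sets = []
    while len(sets) < n:
        b0 = float(rng.uniform(3.0, 40.0))
        sets.append(
            DimensionlessParameters(
                phi2=float(rng.uniform(0.0, 10.0)),
                b0=b0,
                theta=float(rng.uniform(0.2, 20.0)),
                gamma=float(rng.uniform(0.0, 20.0)),
                xi1=float(rng.uniform(0.0, 10.0)),
                xi2=float(rng.uniform(0.0, 10.0)),
                phi_frac=float(rng.uniform(0.0, 2.0)),
            )
        )
    return sets
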