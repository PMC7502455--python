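import numpy as np
import pytest

from laosfit.kinematics import SampleGeometry, TestCondition


@pytest.fixture
def geom():
    """Nominal sample: 3 mm tall, 10 mm radius, 10% compression preload."""
    return SampleGeometry(H=3e-3, R=10e-3, cs=0.10)


@pytest.fixture
def cond(geom):
    """One representative 1 Hz large-shear test at default sampling."""
    return TestCondition(geometry=geom, gamma=0.5, freq=1.0)


@pytest.fixture
def cond_short(geom):
    """Cheap condition for simulation-heavy checks."""
    return TestCondition(
        geometry=geom, gamma=0.25, freq=1.0, points_per_period=64,
        n_burnin=2, n_record=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, scale=0.5):
    """Random symmetric positive definite 3x3 close to identity."""
    A = rng.normal(size=(3, 3)) * scale
    return np.eye(3) + A @ A.T


def random_isochoric_F(rng, scale=0.3):
    """Random unit-determinant deformation gradient near identity."""
    F = np.eye(3) + scale * rng.normal(size=(3, 3))
    return F / np.linalg.det(F) ** (1.0 / 3.0)
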