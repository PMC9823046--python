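"""Shared fixtures: pinned parameter configurations and exact-moment helpers."""

import math

import numpy as np
import pytest

from mrdoc2 import (
    DZ,
    MZ,
    FreePattern,
    GroupMoments,
    MomentData,
    ParamVector,
    StudyDesign,
    exact_moments,
    implied_covariance,
)


def sqrt(v: float) -> float:
    return math.copysign(math.sqrt(abs(v)), v)


@pytest.fixture(scope="session")
def theta_high_power() -> ParamVector:
    """AE configuration with strong instruments and causal paths.

    b1^2 = b3^2 = 0.075, g1^2 = g2^2 = 0.06, uncorrelated backgrounds,
    a^2 = 0.10 for both traits: the highest-power exemplary cell
    (NCP 15.97, power 0.979 at 1000+1000 pairs).
    """
    return ParamVector.standardized(
        b1=sqrt(0.075), b3=sqrt(0.075), g1=sqrt(0.06), g2=sqrt(0.06),
        a1=sqrt(0.10), a2=sqrt(0.10),
    )


@pytest.fixture(scope="session")
def theta_moderate_power() -> ParamVector:
    """Weak-instrument cell with correlated backgrounds (NCP 4.71)."""
    return ParamVector.standardized(
        b1=sqrt(0.025), b3=sqrt(0.05), g1=sqrt(0.06), g2=sqrt(0.02),
        ra=0.5, re=0.25, a1=sqrt(0.10), a2=sqrt(0.10),
    )


@pytest.fixture(scope="session")
def theta_low_power() -> ParamVector:
    """Weak causal paths with strong confounding (NCP 1.13)."""
    return ParamVector.standardized(
        b1=sqrt(0.025), b3=sqrt(0.05), g1=sqrt(0.02), g2=sqrt(0.02),
        rf=0.5, ra=0.5, re=0.5, a1=sqrt(0.25), a2=sqrt(0.25),
    )


@pytest.fixture(scope="session")
def ae_pattern() -> FreePattern:
    return FreePattern.ae()


def exact_data(theta: ParamVector, n_mz: int = 1000, n_dz: int = 1000) -> MomentData:
    return exact_moments(theta, StudyDesign(n_mz=n_mz, n_dz=n_dz, mode="exact"))


def random_admissible_theta(rng: np.random.Generator) -> ParamVector:
    """Draw an admissible full-ACE parameter vector (rejection sampling)."""
    while True:
        theta = ParamVector(
            ra=rng.uniform(-0.6, 0.6), rc=rng.uniform(-0.6, 0.6),
            re=rng.uniform(-0.6, 0.6), rf=rng.uniform(-0.6, 0.6),
            a1=rng.uniform(0.1, 0.7), c1=rng.uniform(0.1, 0.7),
            e1=rng.uniform(0.3, 0.9),
            a2=rng.uniform(0.1, 0.7), c2=rng.uniform(0.1, 0.7),
            e2=rng.uniform(0.3, 0.9),
            g1=rng.uniform(-0.3, 0.3), g2=rng.uniform(-0.3, 0.3),
            b1=rng.uniform(0.1, 0.5), b3=rng.uniform(0.1, 0.5),
            sigma_x=rng.uniform(0.8, 1.25), sigma_y=rng.uniform(0.8, 1.25),
        )
        try:
            for zyg in (MZ, DZ):
                cov = implied_covariance(theta, zyg)
                if np.linalg.eigvalsh(cov)[0] < -1e-10:
                    raise ValueError
        except ValueError:
            continue
        return theta
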