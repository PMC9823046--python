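"""Model-implied moment structure for a twin pair.

The observed 8-vector for a pair is, in fixed order,

    (Ph1_t1, Ph2_t1, PS1_t1, PS2_t1, Ph1_t2, Ph2_t2, PS1_t2, PS2_t2).

Within a twin, the structural equations are

    Ph1 = a1*A1 + c1*C1 + e1*E1 + g2*Ph2 + b1*PS1 + b4*PS2
    Ph2 = a2*A2 + c2*C2 + e2*E2 + g1*Ph1 + b3*PS2 + b2*PS1

so with B = [[0, g2], [g1, 0]] the reduced form multiplies all exogenous
loadings by (I - B)^-1 = 1/(1 - g1*g2) * [[1, g2], [g1, 1]].

Cross-twin covariance follows the biometrical rules: additive-genetic
factors (and polygenic scores, which are additive aggregates of genotype)
covary with coefficient 1 in MZ and 0.5 in DZ pairs, shared-environment
factors with coefficient 1 in both, unique-environment factors with 0.
Cross-trait cross-twin terms carry the same coefficient times the
corresponding factor correlation (ra, rc, rf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DZ, MZ, ParamVector, Zygosity

__all__ = [
    "VARIABLES",
    "ImpliedMoments",
    "PhenotypeSummary",
    "reduced_form",
    "implied_covariance",
    "implied_moments",
    "phenotype_summary",
]

#: Observed-variable order used by every covariance matrix in the package.
VARIABLES = (
    "ph1_t1", "ph2_t1", "ps1_t1", "ps2_t1",
    "ph1_t2", "ph2_t2", "ps1_t2", "ps2_t2",
)

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class ImpliedMoments:
    """Zygosity-specific model-implied moments of the 8-vector of a pair.

    Means are structurally zero; all information sits in ``covariance``,
    ordered as :data:`VARIABLES`.
    """

    covariance: np.ndarray
    mean: np.ndarray
    zygosity: Zygosity

    @property
    def within_twin(self) -> np.ndarray:
        """The 4x4 within-twin block (identical for twin 1 and twin 2)."""
        return self.covariance[:4, :4]

    @property
    def cross_twin(self) -> np.ndarray:
        """The 4x4 cross-twin block."""
        return self.covariance[:4, 4:]


@dataclass(frozen=True)
class PhenotypeSummary:
    """Implied single-twin regression summaries.

    r2_ph1_on_ps1 / r2_ph2_on_ps2: variance of a phenotype explained by its
    own polygenic score (instrument relevance); r2_ph2_ph1: squared
    phenotypic correlation.
    """

    r2_ph1_on_ps1: float
    r2_ph2_on_ps2: float
    r2_ph2_ph1: float


def reduced_form(theta: ParamVector) -> tuple[np.ndarray, np.ndarray]:
    """Reduced form of the reciprocal-causation loop.

    Returns ``(instrument_map, mixing)`` where ``mixing`` is
    (I - B)^-1 with B = [[0, g2], [g1, 0]], and ``instrument_map`` is the
    2x2 matrix of total (direct + loop-mediated) effects of (PS1, PS2) on
    (Ph1, Ph2), i.e. ``mixing @ [[b1, b4], [b2, b3]]``.

    Raises ``ValueError`` when g1*g2 = 1, in which case the loop has no
    stable reduced form.
    """
    det = 1.0 - theta.g1 * theta.g2
    if abs(det) < 1e-12:
        raise ValueError(
            f"g1*g2 = {theta.g1 * theta.g2:.6f}: I - B is singular, the "
            "reciprocal loop admits no reduced form (need g1*g2 != 1)"
        )
    mixing = np.array([[1.0, theta.g2], [theta.g1, 1.0]]) / det
    loadings = np.array([[theta.b1, theta.b4], [theta.b2, theta.b3]])
    return mixing @ loadings, mixing


def _twin_map(theta: ParamVector) -> np.ndarray:
    """4x8 map from per-twin exogenous vector to observed (Ph1,Ph2,PS1,PS2).

    Exogenous order: (A1, C1, E1, A2, C2, E2, PS1, PS2).
    """
    instrument_map, mixing = reduced_form(theta)
    lam = np.array([
        [theta.a1, theta.c1, theta.e1, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, theta.a2, theta.c2, theta.e2],
    ])
    t = np.zeros((4, 8))
    t[:2, :6] = mixing @ lam
    t[:2, 6:] = instrument_map
    t[2, 6] = 1.0
    t[3, 7] = 1.0
    return t


def _exogenous_blocks(theta: ParamVector, zyg: Zygosity) -> tuple[np.ndarray, np.ndarray]:
    """Within-twin and cross-twin covariance of the exogenous 8-vector."""
    k = zyg.genetic_share
    sx, sy = theta.sigma_x, theta.sigma_y
    cov_ps = np.array([
        [sx * sx, theta.rf * sx * sy],
        [theta.rf * sx * sy, sy * sy],
    ])

    within = np.eye(8)
    within[0, 3] = within[3, 0] = theta.ra
    within[1, 4] = within[4, 1] = theta.rc
    within[2, 5] = within[5, 2] = theta.re
    within[6:, 6:] = cov_ps

    cross = np.zeros((8, 8))
    cross[0, 0] = cross[3, 3] = k          # A with A, same trait
    cross[1, 1] = cross[4, 4] = 1.0        # C with C
    cross[0, 3] = cross[3, 0] = k * theta.ra
    cross[1, 4] = cross[4, 1] = theta.rc
    # E factors: no cross-twin covariance
    cross[6:, 6:] = k * cov_ps             # polygenic scores behave like A
    return within, cross


def implied_covariance(theta: ParamVector, zyg: Zygosity) -> np.ndarray:
    """8x8 model-implied covariance of a twin pair, ordered as VARIABLES."""
    theta.validate()
    t = _twin_map(theta)
    within, cross = _exogenous_blocks(theta, zyg)
    sigma_w = t @ within @ t.T
    sigma_c = t @ cross @ t.T
    sigma = np.empty((8, 8))
    sigma[:4, :4] = sigma_w
    sigma[4:, 4:] = sigma_w
    sigma[:4, 4:] = sigma_c
    sigma[4:, :4] = sigma_c.T
    return 0.5 * (sigma + sigma.T)


def implied_moments(theta: ParamVector, zyg: Zygosity) -> ImpliedMoments:
    """Model-implied moments; raises on a non-PSD implied covariance."""
    sigma = implied_covariance(theta, zyg)
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < -_PSD_TOL:
        raise ValueError(
            f"implied {zyg.label} covariance is not positive semidefinite "
            f"(min eigenvalue {min_eig:.3e}); the correlation combination "
            "is inadmissible"
        )
    return ImpliedMoments(covariance=sigma, mean=np.zeros(8), zygosity=zyg)


def phenotype_summary(theta: ParamVector) -> PhenotypeSummary:
    """Implied instrument-relevance and phenotypic-correlation R^2 values."""
    sigma = implied_covariance(theta, MZ)[:4, :4]  # within-twin block, zygosity-free
    v1, v2 = sigma[0, 0], sigma[1, 1]
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero implied phenotype variance; summary undefined")
    return PhenotypeSummary(
        r2_ph1_on_ps1=float(sigma[0, 2] ** 2 / (sigma[2, 2] * v1)),
        r2_ph2_on_ps2=float(sigma[1, 3] ** 2 / (sigma[3, 3] * v2)),
        r2_ph2_ph1=float(sigma[0, 1] ** 2 / (v1 * v2)),
    )
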