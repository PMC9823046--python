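"""Maximum-likelihood fitting to twin-pair moments and LRT power.

Fitting consumes per-zygosity sample covariances (means are structurally
zero), minimising the multigroup normal-theory ML discrepancy

    F(theta) = sum_g n_g * [ ln|Sigma_g(theta)| + tr(S_g Sigma_g(theta)^-1)
                             - ln|S_g| - p ],

which equals the excess of -2 ln L over its saturated-model value.  When the
"data" are exact population moments of the model (exact data simulation),
the full-model minimum is 0 and a constrained fit's minimum is the exact
noncentrality parameter (NCP) of the likelihood-ratio test at the given
sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .model import implied_covariance
from .parameters import DZ, MZ, FreePattern, ParamVector, Zygosity

__all__ = [
    "GroupMoments",
    "MomentData",
    "FitResult",
    "LRTResult",
    "fit_moments",
    "lrt_power",
    "power_from_ncp",
    "default_start",
]

logger = logging.getLogger(__name__)

_P = 8  # observed variables per pair


@dataclass(frozen=True)
class GroupMoments:
    """Sample moments of one zygosity group."""

    covariance: np.ndarray
    mean: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (_P, _P):
            raise ValueError(f"covariance must be {_P}x{_P}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("group covariance is not symmetric")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class MomentData:
    """Per-zygosity moments; either group may be absent (None)."""

    mz: GroupMoments | None
    dz: GroupMoments | None

    def __post_init__(self) -> None:
        if self.mz is None and self.dz is None:
            raise ValueError("at least one zygosity group is required")

    @property
    def total_pairs(self) -> int:
        return (self.mz.n_pairs if self.mz else 0) + (self.dz.n_pairs if self.dz else 0)

    def groups(self) -> list[tuple[Zygosity, GroupMoments]]:
        out = []
        if self.mz is not None:
            out.append((MZ, self.mz))
        if self.dz is not None:
            out.append((DZ, self.dz))
        return out


@dataclass(frozen=True)
class FitResult:
    """ML estimates and discrepancy of one fitted pattern."""

    estimates: ParamVector
    discrepancy: float
    converged: bool
    n_free: int
    pattern: FreePattern

    @property
    def minus_two_log_likelihood_excess(self) -> float:
        return self.discrepancy


@dataclass(frozen=True)
class LRTResult:
    """Noncentrality, degrees of freedom and power of a nested comparison."""

    ncp: float
    df: int
    alpha: float
    power: float


# ---------------------------------------------------------------------------
# discrepancy and gradient

# MZ co-twins carry identical polygenic scores (cross-twin PS correlation is
# exactly 1), so the 8-variable MZ covariance is structurally singular and
# its normal likelihood is improper.  The MZ group is therefore modelled on
# its 6 distinct variables: the four phenotypes plus one pair-level copy of
# each score (taken as the average of the two identical columns, which also
# absorbs any float-level duplication noise in sampled data).
_MZ_REDUCE = np.zeros((6, _P))
for _i, _j in enumerate((0, 1, 4, 5)):       # ph1_t1, ph2_t1, ph1_t2, ph2_t2
    _MZ_REDUCE[_i, _j] = 1.0
_MZ_REDUCE[4, 2] = _MZ_REDUCE[4, 6] = 0.5    # ps1 = mean of the twin copies
_MZ_REDUCE[5, 3] = _MZ_REDUCE[5, 7] = 0.5    # ps2
_DZ_REDUCE = np.eye(_P)


def _reduction(zyg: Zygosity) -> np.ndarray:
    return _MZ_REDUCE if zyg.genetic_share == 1.0 else _DZ_REDUCE


def _group_terms(data: MomentData):
    terms = []
    for zyg, grp in data.groups():
        L = _reduction(zyg)
        s = L @ grp.covariance @ L.T
        sign, logdet_s = np.linalg.slogdet(s)
        if sign <= 0:
            raise ValueError(
                f"{zyg.label} sample covariance is not positive definite "
                "on the group's distinct variables"
            )
        terms.append((zyg, L, s, float(grp.n_pairs), logdet_s))
    return terms


#: Large finite value returned at infeasible points; L-BFGS-B's line search
#: backtracks on finite values but can abort on inf.
_PENALTY = 1e12


def _discrepancy(theta: ParamVector, terms) -> float:
    total = 0.0
    for zyg, L, s, n, logdet_s in terms:
        try:
            sigma = L @ implied_covariance(theta, zyg) @ L.T
            c, low = cho_factor(sigma, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return _PENALTY
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        trace = float(np.trace(cho_solve((c, low), s, check_finite=False)))
        total += n * (logdet + trace - logdet_s - s.shape[0])
    return total


_BOUNDS = {
    "ra": (-0.995, 0.995), "rc": (-0.995, 0.995),
    "re": (-0.995, 0.995), "rf": (-0.995, 0.995),
    # loadings optimise unconstrained in sign: the likelihood is exactly
    # invariant to reflecting a latent factor's axis (loading and attached
    # correlation flip together), and a zero lower bound would create
    # spurious boundary optima when a true loading is small.  Estimates are
    # canonicalised to nonnegative loadings afterwards.
    "a1": (-5.0, 5.0), "c1": (-5.0, 5.0), "e1": (-5.0, 5.0),
    "a2": (-5.0, 5.0), "c2": (-5.0, 5.0), "e2": (-5.0, 5.0),
    "g1": (-0.99, 0.99), "g2": (-0.99, 0.99),
    "b1": (-5.0, 5.0), "b3": (-5.0, 5.0), "b2": (-5.0, 5.0), "b4": (-5.0, 5.0),
    "sigma_x": (1e-6, 10.0), "sigma_y": (1e-6, 10.0),
}


def _canonicalize(theta: ParamVector, pattern: FreePattern) -> ParamVector:
    """Resolve the factor-reflection indeterminacy.

    Flipping a latent factor's axis negates its loading and the cross-trait
    correlation it enters, leaving the likelihood unchanged; the canonical
    representative has nonnegative loadings.  A flip is applied only where
    it is a true symmetry under the pattern: the loading must be free, and
    the attached correlation free (or zero) unless both loadings of the
    pair flip together.
    """
    changes: dict = {}
    for corr, (l1, l2) in (("ra", ("a1", "a2")), ("rc", ("c1", "c2")),
                           ("re", ("e1", "e2"))):
        v1, v2 = getattr(theta, l1), getattr(theta, l2)
        rv = getattr(theta, corr)
        want1 = v1 < 0 and pattern.is_free(l1)
        want2 = v2 < 0 and pattern.is_free(l2)
        if pattern.is_free(corr) or rv == 0.0:
            if want1:
                changes[l1] = -v1
            if want2:
                changes[l2] = -v2
            if want1 != want2 and rv != 0.0:
                changes[corr] = -rv
        elif want1 and want2:  # joint flip leaves the fixed correlation intact
            changes[l1], changes[l2] = -v1, -v2
    return theta.replace(**changes)


#: Plausible ranges for dispersed exploration starts, by parameter kind.
_DISPERSED = {
    "corr": (-0.6, 0.6),
    "loading": (0.1, 0.9),
    "causal": (-0.4, 0.4),
    "instrument": (-0.5, 0.5),
    "sigma": (0.7, 1.4),
}


def _kind(name: str) -> str:
    if name in ("ra", "rc", "re", "rf"):
        return "corr"
    if name[0] in "ace":
        return "loading"
    if name in ("g1", "g2"):
        return "causal"
    if name.startswith("sigma"):
        return "sigma"
    return "instrument"


def default_start(pattern: FreePattern) -> ParamVector:
    """A generic admissible starting point for ML optimisation."""
    start = ParamVector(
        ra=0.1, rc=0.1, re=0.1, rf=0.1,
        a1=0.4, c1=0.3, e1=0.7, a2=0.4, c2=0.3, e2=0.7,
        g1=0.1, g2=0.1, b1=0.15, b3=0.15, b2=0.0, b4=0.0,
        sigma_x=1.0, sigma_y=1.0,
    )
    return pattern.project(start)


def _make_objective(pattern: FreePattern, terms):
    h = 1e-6  # central-difference step for dSigma/dtheta
    lo = np.array([_BOUNDS[n][0] for n in pattern.free_names])
    hi = np.array([_BOUNDS[n][1] for n in pattern.free_names])

    def unpack(x: np.ndarray) -> ParamVector:
        return pattern.build(x)

    def fun(x: np.ndarray) -> float:
        try:
            theta = unpack(x)
        except ValueError:
            return _PENALTY
        return _discrepancy(theta, terms)

    def jac(x: np.ndarray) -> np.ndarray:
        # dF/dx_k = sum_g n_g tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma/dx_k]
        grads = np.zeros_like(x)
        weights = []
        try:
            theta = unpack(x)
            for zyg, L, s, n, _ in terms:
                sigma = L @ implied_covariance(theta, zyg) @ L.T
                c, low = cho_factor(sigma, check_finite=False)
                sigma_inv = cho_solve((c, low), np.eye(s.shape[0]), check_finite=False)
                weights.append((zyg, L, n * (sigma_inv - sigma_inv @ s @ sigma_inv)))
        except (np.linalg.LinAlgError, ValueError):
            # objective is +inf here; the line search backs off on fun alone
            return grads
        for k in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[k] = min(x[k] + h, hi[k])
            xm[k] = max(x[k] - h, lo[k])
            step = xp[k] - xm[k]
            tp, tm = unpack(xp), unpack(xm)
            for zyg, L, w in weights:
                dsig = L @ (implied_covariance(tp, zyg)
                            - implied_covariance(tm, zyg)) @ L.T / step
                grads[k] += float(np.sum(w * dsig))
        return grads

    return fun, jac


def fit_moments(
    data: MomentData,
    pattern: FreePattern,
    start: ParamVector | None = None,
    *,
    max_restarts: int = 6,
    tol: float = 1e-13,
    match_tol: float = 1e-6,
    seed: int = 0,
) -> FitResult:
    """Fit a free/fixed pattern to moment data by maximum likelihood.

    Runs a bounded quasi-Newton (L-BFGS-B) search from ``start`` (default: a
    generic admissible point), then alternates dispersed random starts
    (basin exploration) with jittered restarts around the incumbent
    (confirmation) until the best discrepancy has been reproduced twice
    within ``match_tol`` with at least one dispersed start taken — local
    jitter alone can re-enter the same spurious basin.  An exhausted
    restart budget yields ``converged=False``, never a silent failure.
    """
    terms = _group_terms(data)
    if start is None:
        start = default_start(pattern)
    x0 = pattern.extract(pattern.project(start))
    fun, jac = _make_objective(pattern, terms)
    names = pattern.free_names
    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])
    bounds = list(zip(lo, hi))
    x0 = np.clip(x0, lo, hi)
    disp_lo = np.array([_DISPERSED[_kind(n)][0] for n in names])
    disp_hi = np.array([_DISPERSED[_kind(n)][1] for n in names])

    rng = np.random.default_rng(seed)
    best_x, best_f = None, np.inf
    reproduced = False
    explored = False
    for attempt in range(1 + max_restarts):
        if attempt == 0:
            xi = x0
        elif attempt % 2 == 1:  # dispersed exploration start
            xi = rng.uniform(disp_lo, disp_hi)
            explored = True
        else:  # confirmation jitter around the incumbent
            center = best_x if best_x is not None else x0
            xi = center + rng.normal(scale=0.05 * attempt, size=x0.size)
        xi = np.clip(xi, lo, hi)
        res = optimize.minimize(
            fun, xi, jac=jac, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": tol, "gtol": max(1e-11, 100.0 * tol)},
        )
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        if res.fun < best_f - match_tol:
            best_x, best_f = res.x, float(res.fun)
            reproduced = False
        elif abs(res.fun - best_f) <= match_tol:
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
            reproduced = True
            if attempt >= 1 and explored:
                break
    if best_x is None:
        logger.warning("fit failed to produce a finite discrepancy")
        return FitResult(pattern.build(x0), np.inf, False, pattern.n_free, pattern)
    if not reproduced:
        logger.warning(
            "best discrepancy %.6g not reproduced within %g after %d restarts",
            best_f, match_tol, max_restarts,
        )
    # exact-data fits can dip an epsilon below zero numerically
    best_f = max(best_f, 0.0)
    return FitResult(
        estimates=_canonicalize(pattern.build(best_x), pattern),
        discrepancy=best_f,
        converged=bool(reproduced),
        n_free=pattern.n_free,
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# LRT power


def power_from_ncp(ncp: float, df: int, alpha: float = 0.05) -> float:
    """Power of a chi-square LRT with the given noncentrality.

    The rejection region is the upper alpha tail of the central chi-square
    with ``df`` degrees of freedom; power is the noncentral chi-square mass
    beyond the critical value.  ncp = 0 returns exactly alpha.
    """
    if ncp < 0:
        raise ValueError("ncp must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, ncp))


def lrt_power(full: FitResult, restricted: FitResult, alpha: float = 0.05) -> LRTResult:
    """Noncentrality, df and power of a restricted-vs-full comparison."""
    if not restricted.pattern.is_nested_in(full.pattern):
        raise ValueError("restricted pattern is not nested in the full pattern")
    ncp = restricted.discrepancy - full.discrepancy
    if ncp < -1e-6:
        raise ValueError(
            f"negative noncentrality ({ncp:.3e}): models are not nested or a fit failed"
        )
    ncp = max(ncp, 0.0)
    df = full.n_free - restricted.n_free
    if df < 1:
        raise ValueError("restricted model must have fewer free parameters")
    return LRTResult(ncp=ncp, df=df, alpha=alpha, power=power_from_ncp(ncp, df, alpha))
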