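"""Factorial power designs, NCP regressions and required-N power curves.

Each design cell fixes a full parameter vector; exact data simulation turns
the constrained refits (g1 = 0, g2 = 0, or both) into exact likelihood-ratio
noncentrality parameters at the design's sample sizes, from which chi-square
power follows in closed form.  Regressing the per-cell NCP on the (path
scale) parameter levels decomposes the drivers of statistical power.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .fitting import FitResult, fit_moments, power_from_ncp
from .model import PhenotypeSummary, implied_covariance, phenotype_summary
from .parameters import MZ, FreePattern, ParamVector
from .simulate import StudyDesign, exact_moments

__all__ = [
    "FactorialDesign",
    "PowerCell",
    "NcpRegressionSummary",
    "PowerCurvePoint",
    "design1",
    "design2",
    "design3",
    "run_design",
    "cells_to_frame",
    "regress_ncp",
    "required_n_curve",
    "single_cell",
]

logger = logging.getLogger(__name__)

_TESTS = ("g1", "g2", "joint")


@dataclass(frozen=True)
class FactorialDesign:
    """A full-factorial grid of parameter levels on the path-coefficient scale.

    ``factors`` maps parameter names to their ordered levels (signed square
    roots where the tabled levels are variances); ``fixed`` holds the
    non-varying parameters; e1 and e2 are always derived as
    sqrt(1 - a^2 - c^2).
    """

    factors: dict
    fixed: dict = field(default_factory=dict)
    design_id: str = "custom"

    @property
    def factor_names(self) -> tuple:
        return tuple(self.factors)

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(v) for v in self.factors.values()]))

    def cell_theta(self, index: int) -> ParamVector:
        """Parameter vector of the cell at a flat index (row-major order)."""
        if not 0 <= index < self.n_cells:
            raise IndexError(f"cell index {index} outside 0..{self.n_cells - 1}")
        values = dict(self.fixed)
        names = list(self.factors)
        block = self.n_cells
        rem = index
        for name in names:  # row-major: first factor varies slowest
            block //= len(self.factors[name])
            values[name] = self.factors[name][rem // block]
            rem %= block
        return ParamVector.standardized(**values)

    def iter_cells(self):
        """Yield (index, ParamVector) over all cells in row-major order."""
        names = list(self.factors)
        for index, combo in enumerate(itertools.product(*self.factors.values())):
            values = dict(self.fixed)
            values.update(dict(zip(names, combo)))
            yield index, ParamVector.standardized(**values)

    def subsample(self, k: int, seed: int = 0) -> list:
        """Deterministic random subset of cell indices (without replacement)."""
        rng = np.random.default_rng(seed)
        k = min(k, self.n_cells)
        return sorted(rng.choice(self.n_cells, size=k, replace=False).tolist())

    def fit_pattern(self) -> FreePattern:
        """Free/fixed pattern of the generating ("true") model.

        Parameters fixed at zero in the design (e.g. rc, c1, c2 in the AE
        designs) stay fixed in fitting; everything else in theta is free,
        with the direct pleiotropic paths b2, b4 fixed at zero.
        """
        pattern = FreePattern.full()
        zeros = {
            name: 0.0
            for name, value in self.fixed.items()
            if value == 0.0 and name not in ("b2", "b4")
        }
        return pattern.with_fixed(**zeros)


def _sqrt_levels(*variances: float) -> list:
    return [math.copysign(math.sqrt(abs(v)), v) for v in variances]


def design1() -> FactorialDesign:
    """Two-level ACE design: 12 varying parameters, 2^12 = 4096 cells."""
    f = {
        "b1": _sqrt_levels(0.025, 0.05),
        "b3": _sqrt_levels(0.025, 0.05),
        "g1": _sqrt_levels(0.02, 0.05),
        "g2": _sqrt_levels(0.02, 0.05),
        "ra": [0.25, 0.50],
        "rc": [0.25, 0.50],
        "re": [0.25, 0.50],
        "rf": [0.25, 0.50],
        "a1": _sqrt_levels(0.10, 0.25),
        "a2": _sqrt_levels(0.10, 0.25),
        "c1": _sqrt_levels(0.10, 0.25),
        "c2": _sqrt_levels(0.10, 0.25),
    }
    return FactorialDesign(factors=f, fixed={"sigma_x": 1.0, "sigma_y": 1.0}, design_id="1")


def design2() -> FactorialDesign:
    """AE design with three-level factors: 3^7 * 2^2 = 8748 cells."""
    f = {
        "b1": _sqrt_levels(0.025, 0.05, 0.075),
        "b3": _sqrt_levels(0.025, 0.05, 0.075),
        "g1": _sqrt_levels(0.02, 0.04, 0.06),
        "g2": _sqrt_levels(0.02, 0.04, 0.06),
        "ra": [0.0, 0.25, 0.50],
        "re": [0.0, 0.25, 0.50],
        "rf": [0.0, 0.25, 0.50],
        "a1": _sqrt_levels(0.10, 0.25),
        "a2": _sqrt_levels(0.10, 0.25),
    }
    fixed = {"rc": 0.0, "c1": 0.0, "c2": 0.0, "sigma_x": 1.0, "sigma_y": 1.0}
    return FactorialDesign(factors=f, fixed=fixed, design_id="2")


def design3() -> FactorialDesign:
    """AE design with signed causal and instrument paths: 4^4 = 256 cells."""
    f = {
        "b1": _sqrt_levels(-0.075, -0.03, 0.03, 0.075),
        "b3": _sqrt_levels(-0.075, -0.03, 0.03, 0.075),
        "g1": _sqrt_levels(-0.05, -0.02, 0.05, 0.02),
        "g2": _sqrt_levels(-0.05, -0.02, 0.05, 0.02),
    }
    fixed = {
        "ra": 0.3, "rc": 0.0, "re": 0.3, "rf": 0.3,
        "a1": math.sqrt(0.5), "a2": math.sqrt(0.3),
        "c1": 0.0, "c2": 0.0,
        "sigma_x": 1.0, "sigma_y": 1.0,
    }
    return FactorialDesign(factors=f, fixed=fixed, design_id="3")


@dataclass(frozen=True)
class PowerCell:
    """Per-cell noncentrality parameters, powers and implied summaries."""

    index: int
    theta: ParamVector
    ncp_g1: float
    ncp_g2: float
    ncp_joint: float
    pow_g1: float
    pow_g2: float
    pow_joint: float
    summary: PhenotypeSummary
    error: str | None = None


@dataclass(frozen=True)
class NcpRegressionSummary:
    """Share of NCP variance attributed to each varying parameter.

    ``beta_squared`` holds squared standardized OLS coefficients from the
    regression of the standardized NCP on the standardized (path scale)
    parameter levels; on an orthogonal factorial these equal each factor's
    sum-of-squares share.  ``quadratic_r2_gain`` is the additional R^2 from
    adding squared terms (order=2 only).
    """

    response: str
    beta_squared: dict
    total_r2: float
    quadratic_r2_gain: float | None = None


@dataclass(frozen=True)
class PowerCurvePoint:
    """Required total pair count (even MZ/DZ split) for target power."""

    r2_instrument: float
    b1: float
    ncp_per_pair: float
    n_pairs_80: int
    flagged: bool = False


def _constrained_ncp(
    theta: ParamVector,
    pattern: FreePattern,
    fix: dict,
    study: StudyDesign,
    seed: int,
) -> float:
    data = exact_moments(theta, study)
    constrained = pattern.with_fixed(**fix)
    start = theta.replace(**fix)
    # NCPs are reported to ~1e-3; a looser objective tolerance than the
    # parameter-recovery default keeps large factorial runs affordable
    result = fit_moments(data, constrained, start=start, seed=seed,
                         max_restarts=4, tol=1e-9)
    if not result.converged:
        raise RuntimeError(
            f"constrained fit ({', '.join(fix)}) did not reproduce its optimum"
        )
    return result.discrepancy


def single_cell(
    theta: ParamVector,
    pattern: FreePattern,
    study: StudyDesign | None = None,
    alpha: float = 0.05,
    index: int = 0,
    tests: tuple = _TESTS,
) -> PowerCell:
    """Exact NCP and power of the causal-parameter tests for one cell."""
    study = study or StudyDesign()
    ncps = {t: float("nan") for t in _TESTS}
    error = None
    try:
        fixes = {"g1": {"g1": 0.0}, "g2": {"g2": 0.0}, "joint": {"g1": 0.0, "g2": 0.0}}
        for t in tests:
            ncps[t] = _constrained_ncp(theta, pattern, fixes[t], study, seed=index)
    except (RuntimeError, ValueError) as exc:
        error = str(exc)
    pows = {
        t: power_from_ncp(ncps[t], 2 if t == "joint" else 1, alpha)
        if np.isfinite(ncps[t]) else float("nan")
        for t in _TESTS
    }
    return PowerCell(
        index=index, theta=theta,
        ncp_g1=ncps["g1"], ncp_g2=ncps["g2"], ncp_joint=ncps["joint"],
        pow_g1=pows["g1"], pow_g2=pows["g2"], pow_joint=pows["joint"],
        summary=phenotype_summary(theta), error=error,
    )


def run_design(
    design: FactorialDesign,
    study: StudyDesign | None = None,
    alpha: float = 0.05,
    cells: list | None = None,
    tests: tuple = _TESTS,
) -> list:
    """Run (a subset of) a factorial design; deterministic given the design.

    ``cells`` restricts the run to the given flat indices (e.g. from
    :meth:`FactorialDesign.subsample`); per-cell fit failures are recorded
    on the cell and the run continues.
    """
    study = study or StudyDesign()
    pattern = design.fit_pattern()
    wanted = set(cells) if cells is not None else None
    out = []
    for index, theta in design.iter_cells():
        if wanted is not None and index not in wanted:
            continue
        out.append(single_cell(theta, pattern, study, alpha, index, tests))
    n_failed = sum(1 for c in out if c.error)
    if n_failed:
        logger.warning("%d of %d cells failed to fit", n_failed, len(out))
    return out


def cells_to_frame(cells: list) -> pd.DataFrame:
    """Flatten PowerCells into a table (one row per cell)."""
    rows = []
    for c in cells:
        row = {"cell": c.index}
        row.update(c.theta.as_dict())
        row.update(
            ncp_g1=c.ncp_g1, ncp_g2=c.ncp_g2, ncp_joint=c.ncp_joint,
            pow_g1=c.pow_g1, pow_g2=c.pow_g2, pow_joint=c.pow_joint,
            r2_ph1_on_ps1=c.summary.r2_ph1_on_ps1,
            r2_ph2_on_ps2=c.summary.r2_ph2_on_ps2,
            r2_ph2_ph1=c.summary.r2_ph2_ph1,
            error=c.error or "",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def regress_ncp(cells: list, response: str = "g1", order: int = 1) -> NcpRegressionSummary:
    """Decompose NCP variance over the varying parameters by standardized OLS.

    Parameter levels enter on the path-coefficient scale (the theta scale:
    signed square roots of tabled variance levels), which is the only coding
    that distinguishes the signed levels of the third design.
    """
    if response not in _TESTS:
        raise ValueError(f"response must be one of {_TESTS}")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    good = [c for c in cells if not c.error and np.isfinite(getattr(c, f"ncp_{response}"))]
    if len(good) < 3:
        raise ValueError("need at least 3 successfully fitted cells")
    y = np.array([getattr(c, f"ncp_{response}") for c in good])
    if y.std(ddof=0) == 0:
        # no NCP variance: every share is zero by convention
        varying = _varying_factors(good)
        return NcpRegressionSummary(
            response=response,
            beta_squared={name: 0.0 for name in varying},
            total_r2=0.0,
            quadratic_r2_gain=0.0 if order == 2 else None,
        )
    varying = _varying_factors(good)
    if not varying:
        raise ValueError("no varying parameters across cells")
    cols, names = [], []
    for name in varying:
        col = np.array([getattr(c.theta, name) for c in good])
        cols.append(_standardize(col))
        names.append(name)
    x = np.column_stack(cols)
    _check_collinear(x, names)
    y_std = _standardize(y)
    fit1 = sm.OLS(y_std, sm.add_constant(x)).fit()
    beta_sq = {n: float(b * b) for n, b in zip(names, fit1.params[1:])}
    total_r2 = float(fit1.rsquared)
    gain = None
    if order == 2:
        x2 = np.column_stack([_standardize(c * c) if len(np.unique(np.round(c * c, 12))) > 1
                              else np.zeros_like(c) for c in cols])
        keep = [j for j in range(x2.shape[1]) if x2[:, j].std() > 0]
        xq = np.column_stack([x] + ([x2[:, keep]] if keep else []))
        fit2 = sm.OLS(y_std, sm.add_constant(xq)).fit()
        gain = float(fit2.rsquared - fit1.rsquared)
    return NcpRegressionSummary(
        response=response, beta_squared=beta_sq, total_r2=total_r2, quadratic_r2_gain=gain
    )


def _varying_factors(cells: list) -> list:
    varying = []
    from .parameters import PARAM_NAMES

    for name in PARAM_NAMES:
        if name in ("e1", "e2"):  # derived from a and c, collinear by construction
            continue
        values = {round(getattr(c.theta, name), 12) for c in cells}
        if len(values) > 1:
            varying.append(name)
    return varying


def _check_collinear(x: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(x, tol=1e-8)
    if rank < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(f"collinear design; offending factors: {pairs or names}")


def required_n_curve(
    theta_base: ParamVector,
    r2_grid: list,
    target_power: float = 0.80,
    alpha: float = 0.05,
    pattern: FreePattern | None = None,
) -> list:
    """Required total twin pairs (even MZ/DZ split) to reject g1 = 0.

    For each target instrument R^2 (variance of Ph1 explained by PS1) the
    instrument path b1 is solved so the implied R^2 matches, the exact NCP
    is evaluated once at a reference sample size, and the linearity of the
    NCP in the pair count gives the smallest (even) total N whose power
    reaches ``target_power``.  A point whose per-pair NCP is zero is
    flagged instead of looped on.
    """
    pattern = pattern or _pattern_for(theta_base)
    ref = StudyDesign(n_mz=1000, n_dz=1000)
    # smallest ncp whose 1-df test reaches the target power
    ncp_star = optimize.brentq(
        lambda v: power_from_ncp(v, 1, alpha) - target_power, 1e-9, 100.0
    )
    points = []
    for r2 in r2_grid:
        b1 = _solve_b1(theta_base, r2)
        theta = theta_base.replace(b1=b1)
        ncp_ref = _constrained_ncp(theta, pattern, {"g1": 0.0}, ref, seed=0)
        per_pair = ncp_ref / (ref.n_mz + ref.n_dz)
        if per_pair <= 0:
            points.append(PowerCurvePoint(r2, b1, 0.0, 0, flagged=True))
            continue
        n = int(math.ceil(ncp_star / (2 * per_pair))) * 2
        # guard against rounding at the boundary
        while power_from_ncp((n - 2) * per_pair, 1, alpha) >= target_power and n > 2:
            n -= 2
        while power_from_ncp(n * per_pair, 1, alpha) < target_power:
            n += 2
        points.append(PowerCurvePoint(r2, b1, per_pair, n))
    return points


def _pattern_for(theta: ParamVector) -> FreePattern:
    pattern = FreePattern.full()
    zeros = {
        n: 0.0 for n in ("rc", "c1", "c2")
        if getattr(theta, n) == 0.0
    }
    return pattern.with_fixed(**zeros)


def _solve_b1(theta_base: ParamVector, r2_target: float) -> float:
    if not 0 < r2_target < 1:
        raise ValueError("target R^2 must be in (0, 1)")

    def gap(b1: float) -> float:
        return phenotype_summary(theta_base.replace(b1=b1)).r2_ph1_on_ps1 - r2_target

    return optimize.brentq(gap, 0.0, 5.0)
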