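"""scikit-learn style estimator wrapping the ML fitting core.

``MRDoC2Model`` follows the sklearn estimator contract (``get_params`` /
``set_params``, ``fit``, fitted attributes with trailing underscores) so it
composes with sklearn tooling; it is a covariance-structure model, so there
is no ``predict`` — ``score`` returns the negative ML discrepancy on new
data, higher is better.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import MomentData, fit_moments, lrt_power
from .io import moments_from_table
from .parameters import FreePattern, ParamVector

__all__ = ["MRDoC2Model"]


class MRDoC2Model(BaseEstimator):
    """Reciprocal-causation twin model with polygenic-score instruments.

    Parameters
    ----------
    pattern : FreePattern or None
        Free/fixed status of the parameters.  None means the canonical
        identified model: everything free, direct pleiotropic paths
        b2 = b4 = 0.
    start : ParamVector or None
        Starting point for the optimizer; None uses a generic admissible
        point.
    max_restarts : int
        Jittered restarts allowed while reproducing the best discrepancy.
    tol : float
        Objective convergence tolerance.
    random_state : int
        Seed for restart jitter.

    Attributes
    ----------
    params_ : ParamVector
        Maximum-likelihood estimates.
    discrepancy_ : float
        ML discrepancy (the excess of -2 ln L over the saturated model).
    converged_ : bool
        Whether the optimum was reproduced from independent starts.
    n_free_ : int
        Number of freely estimated parameters.
    result_ : FitResult
        The full fit result.
    """

    def __init__(
        self,
        pattern: FreePattern | None = None,
        start: ParamVector | None = None,
        max_restarts: int = 6,
        tol: float = 1e-10,
        random_state: int = 0,
    ) -> None:
        self.pattern = pattern
        self.start = start
        self.max_restarts = max_restarts
        self.tol = tol
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _resolved_pattern(self) -> FreePattern:
        return self.pattern if self.pattern is not None else FreePattern.full()

    @staticmethod
    def _as_moments(X) -> MomentData:
        if isinstance(X, MomentData):
            return X
        if isinstance(X, pd.DataFrame):
            return moments_from_table(X)
        raise TypeError(
            "X must be a wide-format twin-pair DataFrame or a MomentData; "
            f"got {type(X).__name__}"
        )

    # -- estimator API --------------------------------------------------------

    def fit(self, X, y=None) -> "MRDoC2Model":
        """Fit by maximum likelihood.

        ``X`` is either a wide twin-pair table (columns pair_id, zygosity,
        ph1_t1 ... ps2_t2) or pre-computed :class:`MomentData`; ``y`` is
        ignored (present for sklearn API compatibility).
        """
        data = self._as_moments(X)
        result = fit_moments(
            data,
            self._resolved_pattern(),
            start=self.start,
            max_restarts=self.max_restarts,
            tol=self.tol,
            seed=self.random_state,
        )
        self.result_ = result
        self.params_ = result.estimates
        self.discrepancy_ = result.discrepancy
        self.converged_ = result.converged
        self.n_free_ = result.n_free
        return self

    def score(self, X, y=None) -> float:
        """Negative ML discrepancy of the fitted parameters on ``X``."""
        from .fitting import _discrepancy, _group_terms  # internal reuse

        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        return -float(_discrepancy(self.params_, _group_terms(self._as_moments(X))))

    def lrt(self, X, null_pattern: FreePattern, alpha: float = 0.05):
        """Likelihood-ratio comparison against a nested null pattern on ``X``."""
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        data = self._as_moments(X)
        null = fit_moments(
            data, null_pattern, start=self.params_,
            max_restarts=self.max_restarts, tol=self.tol, seed=self.random_state,
        )
        return lrt_power(self.result_, null, alpha)
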