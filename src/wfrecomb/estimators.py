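"""Scikit-learn-style estimator classes over the path functionals.

Each estimator consumes an observed :class:`~wfrecomb.simulate.Trajectory`
in ``fit`` and exposes fitted attributes with a trailing underscore.  The
classes subclass :class:`sklearn.base.BaseEstimator` so ``get_params`` /
``set_params`` and ``clone`` work; note the "sample" here is a whole
diffusion path rather than a feature matrix, so pipeline composition is
limited to parameter management and model selection over estimator
settings.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .params import ModelParams
from .model import marginals
from .simulate import Trajectory
from . import functionals as fn
from .lrt import TestResult, test_recombination


def _as_trajectory(X) -> Trajectory:
    if isinstance(X, Trajectory):
        return X
    raise TypeError(
        "expected a wfrecomb.simulate.Trajectory; load one with "
        "Trajectory.from_csv or simulate with euler_maruyama")


class RecombinationMLE(BaseEstimator):
    """MLE of the two-locus recombination rate from an observed path.

    Parameters
    ----------
    params : ModelParams, optional
        Nuisance-drift specification (mutation rates/matrices, optional
        selection treated as known).  Defaults to the parameters attached
        to the fitted trajectory.
    convention : {"limit_at_S", "truth_assigned"}
        Valuation of paths whose information exploded.  ``truth_assigned``
        (simulation experiments only) requires ``true_rho``.
    true_rho : float, optional
        True rate, for the ``truth_assigned`` convention.
    eps : float
        Optional frequency floor restricting the integrands to
        ``eps <= X_ij <= 1 - eps`` (0 disables; the model convention).

    Attributes
    ----------
    rho_ : float
        Corrected MLE on [0, inf).
    raw_ : float
        Unrectified Y / I_T.
    information_ : float
        Observed information accumulated to ``t_eff_``.
    score_ : float
        Score integral Y.
    exploded_ : bool
    explosion_time_ : float or None
    t_eff_ : float
    """

    def __init__(self, params: Optional[ModelParams] = None,
                 convention: str = "limit_at_S",
                 true_rho: Optional[float] = None, eps: float = 0.0):
        self.params = params
        self.convention = convention
        self.true_rho = true_rho
        self.eps = eps

    def fit(self, X, y=None):
        traj = _as_trajectory(X)
        params = self.params or traj.params
        pf = fn.path_functionals(traj, params, eps=self.eps)
        est = fn.rho_mle_corrected(
            traj, params, convention=self.convention, true_rho=self.true_rho)
        self.functionals_ = pf
        self.estimate_ = est
        self.rho_ = est.value
        self.raw_ = est.raw
        self.information_ = pf.I_T
        self.score_ = pf.Y
        self.exploded_ = pf.exploded
        self.explosion_time_ = pf.S
        self.t_eff_ = pf.T_eff
        return self

    def loglik(self, rho) -> float:
        """Profile the quadratic log-likelihood at the given rate(s)."""
        return self.functionals_.loglik(rho)

    def lrt(self, level: float = 0.05) -> TestResult:
        """Likelihood-ratio test of rho_0 = 0 with the boundary-mixture null."""
        return test_recombination(self.estimate_, self.functionals_, level)


class SelectionMLE(BaseEstimator):
    """Genic selection estimator for one allele at locus A.

    Fitted attribute ``s_`` is the path estimator
    ``2 (Xtilde_{k.}(T) - X_{k.}(0)) / int X_{k.} (1 - X_{k.}) dt``.
    """

    def __init__(self, params: Optional[ModelParams] = None, allele: int = 0):
        self.params = params
        self.allele = allele

    def fit(self, X, y=None):
        traj = _as_trajectory(X)
        est = fn.selection_estimator(traj, self.params or traj.params,
                                     k=self.allele)
        self.estimate_ = est
        self.s_ = est.value
        self.exploded_ = est.exploded
        self.t_eff_ = est.T_eff
        return self


class JointRecombinationSelectionMLE(BaseEstimator):
    """Joint fit of (rho, s_k) for genic selection on one locus-A allele.

    The observed information matrix of this model is diagonal, so the
    recombination component coincides with the marginal recombination
    estimator and the selection component with the marginal selection
    estimator; the class exposes the full 2 x 2 information for inspection.
    """

    def __init__(self, params: Optional[ModelParams] = None, allele: int = 0):
        self.params = params
        self.allele = allele

    def fit(self, X, y=None):
        traj = _as_trajectory(X)
        params = self.params or traj.params
        K, L = params.K, params.L
        k = self.allele

        def Z_fn(x):
            p, q = marginals(x, K, L)
            z_rho = np.outer(p, q).ravel() - x
            delta = np.repeat(np.eye(K)[k], L)
            z_sel = 0.5 * x * (delta - p[k])
            return np.stack([z_rho, z_sel], axis=1)

        est, pf = fn.generic_linear_mle(
            traj, Z_fn, c_fn=lambda x: fn.nuisance_drift(x, params), r=2)
        self.estimate_ = est
        self.functionals_ = pf
        self.rho_ = float(np.maximum(0.0, est.value[0]))
        self.raw_rho_ = float(est.value[0])
        self.s_ = float(est.value[1])
        self.information_ = pf.I_T
        self.exploded_ = pf.exploded
        return self


class MultilocusRecombinationMLE(BaseEstimator):
    """Inter-locus recombination rates for an l-locus model.

    ``mode='joint'`` estimates the vector ``(rho_1, ..., rho_{l-1})``;
    ``mode='shared'`` a single shared rate.  Both reduce to the two-locus
    estimator for l = 2 and are boundary-corrected like the scalar case.
    """

    def __init__(self, params: Optional[ModelParams] = None,
                 mode: str = "joint", convention: str = "limit_at_S",
                 true_rho=None):
        self.params = params
        self.mode = mode
        self.convention = convention
        self.true_rho = true_rho

    def fit(self, X, y=None):
        traj = _as_trajectory(X)
        params = self.params or traj.params
        if self.mode == "joint":
            est = fn.multilocus_joint_estimator(
                traj, params, convention=self.convention,
                true_rho=self.true_rho)
        elif self.mode == "shared":
            est = fn.multilocus_shared_estimator(
                traj, params, convention=self.convention,
                true_rho=self.true_rho)
        else:
            raise ValueError("mode must be 'joint' or 'shared'")
        self.estimate_ = est
        self.rho_ = est.value
        self.raw_ = est.raw
        self.information_ = est.I_T
        self.exploded_ = est.exploded
        return self
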