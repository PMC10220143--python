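"""Likelihood functionals of an observed diffusion path.

For a drift that is linear in its unknown parameters,
``a_i(x; phi) = sum_k Z_ik(x) phi_k``, the log-likelihood of the observed
path against the reference model (``phi = 0``) is the quadratic

    log L_T(phi) = phi' Y - 1/2 phi' I_T phi,

with score vector ``Y_k = int sum_i Z_ik / X_i dXtilde_i`` and observed
information ``I_kl = int sum_i Z_ik Z_il / X_i dt``, where
``Xtilde(t) = X(t) - int_0^t c(X(s)) ds`` compensates the path for the known
drift.  The maximizer is ``phi_hat = I_T^{-1} Y``.

All stochastic integrals are evaluated as left-point (Ito-consistent)
Riemann sums on the trajectory grid, matching the Euler-Maruyama
discretization.  Integrals stop at the last grid point at which every
haplotype frequency is strictly positive: hitting zero makes the
information explode, the discrete proxy for the stopping time S, after
which the running estimator has already converged to the truth (the
boundary-corrected estimator equals the true rate with probability one on
that event).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .params import ModelParams
from .model import (
    linkage_disequilibrium,
    marginals,
    multilocus_marginals,
    nuisance_drift,
    sigma_pal_dot,
)
from .simulate import Trajectory

__all__ = [
    "PathFunctionals",
    "Estimate",
    "xtilde_increments",
    "observed_information",
    "score_integral",
    "path_functionals",
    "rho_hat",
    "rho_mle_corrected",
    "generic_linear_mle",
    "selection_estimator",
    "multilocus_joint_estimator",
    "multilocus_shared_estimator",
    "error_decomposition",
    "loglikelihood",
]


@dataclass
class PathFunctionals:
    """Sufficient statistics (Y, I_T) of the quadratic log-likelihood."""

    Y: float | np.ndarray
    I_T: float | np.ndarray
    T_eff: float
    exploded: bool
    S: Optional[float] = None

    def loglik(self, phi) -> float:
        """Evaluate ``log L_T(phi) = phi' Y - 1/2 phi' I_T phi``."""
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        Y = np.atleast_1d(np.asarray(self.Y, dtype=float))
        I = np.atleast_2d(np.asarray(self.I_T, dtype=float))
        return float(phi @ Y - 0.5 * phi @ I @ phi)


@dataclass
class Estimate:
    """A (possibly boundary-corrected) parameter estimate.

    ``raw`` is the unconstrained maximizer Y / I_T (may be negative);
    ``value`` is the estimate after rectification onto the parameter space
    and the exploded-replicate convention.  ``convention`` records how an
    exploded path was valued: ``limit_at_S`` (limit of the running
    estimator just before the explosion) or ``truth_assigned`` (the true
    parameter, justified for experiments by the exactness of the corrected
    estimator upon explosion).
    """

    value: float | np.ndarray
    raw: float | np.ndarray
    exploded: bool
    convention: str = "limit_at_S"
    I_T: float | np.ndarray = np.nan
    T_eff: float = np.nan
    S: Optional[float] = None


# ----------------------------------------------------------------- helpers
def _full_resolution(traj: Trajectory) -> None:
    if traj.thin_stride != 1:
        raise ValueError(
            "path functionals require a full-resolution trajectory "
            "(thin_stride == 1); use the streaming experiment kernel for "
            "thinned storage")


def _n_valid_states(traj: Trajectory) -> int:
    """Grid points usable by the integrals (strictly interior prefix)."""
    if traj.explosion_step is not None:
        return traj.explosion_step
    return len(traj.times)


def _default_c(params: Optional[ModelParams]) -> Callable[[np.ndarray], np.ndarray]:
    if params is None:
        return lambda x: np.zeros_like(x)
    return lambda x: nuisance_drift(x, params)


def xtilde_increments(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    c_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Compensated increments ``dXtilde_n = X_{n+1} - X_n - c(X_n) dt_n``.

    Computed over the whole stored grid; consumers slice to the
    pre-explosion segment.  ``c_fn`` overrides the nuisance drift implied by
    ``params`` (mutation, plus selection when declared).
    """
    _full_resolution(traj)
    c_fn = c_fn or _default_c(params if params is not None else traj.params)
    X = traj.X
    dts = np.diff(traj.times)
    C = np.stack([c_fn(x) for x in X[:-1]])
    return np.diff(X, axis=0) - C * dts[:, None]


# ------------------------------------------------- two-locus recombination
def _rho_weights(X: np.ndarray, K: int, L: int, eps: float = 0.0):
    """Integrand pieces at each grid point for the recombination problem.

    Returns ``w = x_{i.} x_{.j} / x_ij`` (score weight) and ``g = sum D^2/x``
    (information integrand).  With ``eps > 0`` the per-haplotype terms are
    restricted to times at which ``eps <= x_ij <= 1 - eps``.
    """
    P = X.reshape(len(X), K, L)
    p = P.sum(axis=2)
    q = P.sum(axis=1)
    pq = p[:, :, None] * q[:, None, :]
    pq = pq.reshape(len(X), K * L)
    D = X - pq
    mask = np.ones_like(X) if eps == 0.0 else (
        (X >= eps) & (X <= 1.0 - eps)).astype(float)
    w = mask * pq / X
    g = (mask * D * D / X).sum(axis=1)
    return w, g, D


def observed_information(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    form: str = "direct",
    eps: float = 0.0,
) -> float:
    """Observed information for the two-locus recombination rate.

    ``form='direct'`` integrates ``sum_ij (X_ij - X_{i.} X_{.j})^2 / X_ij``;
    ``form='expanded'`` uses the algebraically identical
    ``int sum_ij X_{i.}^2 X_{.j}^2 / X_ij dt - T_eff``.  Both are left-point
    Riemann sums restricted to the pre-explosion segment, hence agree to
    rounding error.
    """
    _full_resolution(traj)
    params = params or traj.params
    K, L = params.K, params.L
    m = _n_valid_states(traj)
    X = traj.X[: m]
    dts = np.diff(traj.times[: m])
    w, g, _ = _rho_weights(X[:-1], K, L, eps)
    if form == "direct":
        return float(g @ dts)
    if form == "expanded":
        P = X[:-1].reshape(-1, K, L)
        p = P.sum(axis=2)
        q = P.sum(axis=1)
        pq2 = (p[:, :, None] * q[:, None, :]).reshape(-1, K * L) ** 2
        integrand = (pq2 / X[:-1]).sum(axis=1)
        return float(integrand @ dts - dts.sum())
    raise ValueError(f"unknown form {form!r}")


def score_integral(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    eps: float = 0.0,
) -> float:
    """Score integral ``Y = int sum_ij (X_{i.} X_{.j} / X_ij) dXtilde_ij``.

    Left-point rule: the integrand is evaluated at the left grid point of
    each increment.  Equivalently ``Y = -int sum_i (D_i / X_i) dXtilde_i``
    since the compensated increments sum to zero over haplotypes.
    """
    _full_resolution(traj)
    params = params or traj.params
    K, L = params.K, params.L
    m = _n_valid_states(traj)
    dxt = xtilde_increments(traj, params)[: m - 1]
    w, _, _ = _rho_weights(traj.X[: m - 1], K, L, eps)
    return float(np.sum(w * dxt))


def path_functionals(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    eps: float = 0.0,
) -> PathFunctionals:
    """Accumulate (Y, I_T) for the two-locus recombination problem."""
    params = params or traj.params
    m = _n_valid_states(traj)
    return PathFunctionals(
        Y=score_integral(traj, params, eps),
        I_T=observed_information(traj, params, eps=eps),
        T_eff=float(traj.times[m - 1]),
        exploded=traj.exploded,
        S=traj.explosion_time,
    )


def rho_hat(
    traj: Trajectory, params: Optional[ModelParams] = None, eps: float = 0.0
) -> float:
    """Raw (unrectified) recombination-rate estimator ``Y / I_T``."""
    pf = path_functionals(traj, params, eps)
    if pf.I_T == 0.0:
        raise ZeroDivisionError(
            "undefined estimator: the path carries no information "
            "(identically at linkage equilibrium)")
    return pf.Y / pf.I_T


def rho_mle_corrected(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    convention: str = "limit_at_S",
    true_rho: Optional[float] = None,
) -> Estimate:
    """Boundary-corrected MLE on the parameter space [0, inf).

    Non-exploded paths: ``max(0, rho_hat)``.  Exploded paths: under
    ``limit_at_S`` the estimator computed on the pre-explosion segment
    (rectified, since discretization noise can push the limit slightly
    negative); under ``truth_assigned`` (experiments only) the true rate is
    recorded as the zero-error value, justified by the exactness of the
    corrected estimator on the explosion event.
    """
    if convention not in ("limit_at_S", "truth_assigned"):
        raise ValueError(f"unknown convention {convention!r}")
    pf = path_functionals(traj, params)
    raw = pf.Y / pf.I_T if pf.I_T > 0 else 0.0
    if pf.exploded and convention == "truth_assigned":
        if true_rho is None:
            raise ValueError("truth_assigned convention requires true_rho")
        value = float(true_rho)
    else:
        value = max(0.0, raw)
    return Estimate(
        value=value,
        raw=raw,
        exploded=pf.exploded,
        convention=convention,
        I_T=pf.I_T,
        T_eff=pf.T_eff,
        S=pf.S,
    )


# ------------------------------------------------------ generic linear MLE
def generic_linear_mle(
    traj: Trajectory,
    Z_fn: Callable[[np.ndarray], np.ndarray],
    c_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    r: int = 1,
) -> Tuple[Estimate, PathFunctionals]:
    """MLE for any drift linear in its parameters: solves ``I_T phi = Y``.

    ``Z_fn(x)`` returns the d x r matrix of parameter derivatives of the
    drift; its columns must be linearly independent along the path.  For the
    single-parameter recombination score this reproduces the dedicated
    estimator exactly.
    """
    _full_resolution(traj)
    m = _n_valid_states(traj)
    X = traj.X[: m]
    dts = np.diff(traj.times[: m])
    dxt = xtilde_increments(traj, traj.params, c_fn=c_fn)[: m - 1]
    Y = np.zeros(r)
    I = np.zeros((r, r))
    for n in range(m - 1):
        Z = np.atleast_2d(np.asarray(Z_fn(X[n]), dtype=float))
        if Z.shape[0] != traj.d:
            Z = Z.T
        W = Z / X[n][:, None]
        Y += W.T @ dxt[n]
        I += (Z.T @ W) * dts[n]
    if r == 1:
        if I[0, 0] == 0.0:
            raise np.linalg.LinAlgError("singular information: zero integrand")
        phi = Y / I[0, 0]
    else:
        try:
            phi = np.linalg.solve(I, Y)
        except np.linalg.LinAlgError:
            evals, evecs = np.linalg.eigh(I)
            k = int(np.argmin(np.abs(evals)))
            raise np.linalg.LinAlgError(
                "singular information matrix; deficient direction "
                f"{np.round(evecs[:, k], 6)} (eigenvalue {evals[k]:.3e})")
    T_eff = float(traj.times[m - 1])
    pf = PathFunctionals(
        Y=Y if r > 1 else float(Y[0]),
        I_T=I if r > 1 else float(I[0, 0]),
        T_eff=T_eff,
        exploded=traj.exploded,
        S=traj.explosion_time,
    )
    est = Estimate(
        value=phi if r > 1 else float(phi[0]),
        raw=phi if r > 1 else float(phi[0]),
        exploded=traj.exploded,
        I_T=pf.I_T,
        T_eff=T_eff,
        S=traj.explosion_time,
    )
    return est, pf


# ------------------------------------------------------- selection special
def selection_estimator(
    traj: Trajectory, params: Optional[ModelParams] = None, k: int = 0
) -> Estimate:
    """Genic selection estimator for allele ``k`` at locus A.

    ``s_hat = 2 (Xtilde_{k.}(T) - X_{k.}(0)) / int X_{k.} (1 - X_{k.}) dt``
    where the numerator uses the locus-A marginal of the compensated path.
    Equals the selection component of the joint (rho, s) fit; with no
    mutation it is the classical single-locus path estimator for selection.
    """
    _full_resolution(traj)
    params = params or traj.params
    K, L = params.K, params.L
    m = _n_valid_states(traj)
    X = traj.X[: m]
    dts = np.diff(traj.times[: m])
    pk = X.reshape(-1, K, L).sum(axis=2)[:, k]
    denom = float((pk[:-1] * (1.0 - pk[:-1])) @ dts)
    if denom == 0.0:
        raise ZeroDivisionError(
            "selection estimator undefined: marginal fixed at 0 or 1")
    dxt = xtilde_increments(traj, params)[: m - 1]
    dxt_k = dxt.reshape(-1, K, L).sum(axis=2)[:, k]
    s = 2.0 * float(dxt_k.sum()) / denom
    return Estimate(
        value=s,
        raw=s,
        exploded=traj.exploded,
        I_T=denom / 4.0,
        T_eff=float(traj.times[m - 1]),
        S=traj.explosion_time,
    )


# ------------------------------------------------------------- multi-locus
def _multilocus_Z(params: ModelParams) -> Callable[[np.ndarray], np.ndarray]:
    counts = params.allele_counts
    ell = len(counts)

    def Z_fn(x: np.ndarray) -> np.ndarray:
        cols = []
        for j in range(1, ell):
            pre, suf = multilocus_marginals(x, counts, j)
            cols.append(pre * suf - x)
        return np.stack(cols, axis=1)

    return Z_fn


def multilocus_joint_estimator(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    convention: str = "limit_at_S",
    true_rho=None,
) -> Estimate:
    """Joint MLE for the inter-locus rates ``(rho_1, ..., rho_{l-1})``.

    Solves the (l-1)-dimensional system ``I_T rho_hat = Y`` with scores
    ``Z_j = x_{i<=j} x_{i>j} - x_i`` and applies the boundary correction
    componentwise.  Reduces to the two-locus estimator when l = 2.
    """
    params = params or traj.params
    r = params.num_loci - 1
    est, pf = generic_linear_mle(traj, _multilocus_Z(params), r=r)
    raw = np.atleast_1d(np.asarray(est.raw, dtype=float))
    if pf.exploded and convention == "truth_assigned":
        if true_rho is None:
            raise ValueError("truth_assigned convention requires true_rho")
        value = np.atleast_1d(np.asarray(true_rho, dtype=float)).copy()
    else:
        value = np.maximum(0.0, raw)
    if r == 1:
        value, raw = float(value[0]), float(raw[0])
    return Estimate(
        value=value, raw=raw, exploded=pf.exploded, convention=convention,
        I_T=pf.I_T, T_eff=pf.T_eff, S=pf.S)


def multilocus_shared_estimator(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    convention: str = "limit_at_S",
    true_rho: Optional[float] = None,
) -> Estimate:
    """Scalar MLE under a shared rate ``rho_j = rho`` for every cut.

    ``rho_hat = sum_j Y_j / sum_{j,k} I_jk`` built from the same score and
    information elements as the joint fit.
    """
    params = params or traj.params
    r = params.num_loci - 1
    _, pf = generic_linear_mle(traj, _multilocus_Z(params), r=r)
    Y = np.atleast_1d(np.asarray(pf.Y, dtype=float))
    I = np.atleast_2d(np.asarray(pf.I_T, dtype=float))
    denom = float(I.sum())
    if denom == 0.0:
        raise ZeroDivisionError("undefined estimator: zero total information")
    raw = float(Y.sum()) / denom
    if pf.exploded and convention == "truth_assigned":
        if true_rho is None:
            raise ValueError("truth_assigned convention requires true_rho")
        value = float(true_rho)
    else:
        value = max(0.0, raw)
    return Estimate(
        value=value, raw=raw, exploded=pf.exploded, convention=convention,
        I_T=denom, T_eff=pf.T_eff, S=pf.S)


# ------------------------------------------------------ error decomposition
def error_decomposition(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    true_rho: Optional[float] = None,
) -> Tuple[float, float]:
    """Martingale error decomposition of the raw estimator.

    Returns ``(N_T, predicted_error)`` with
    ``N_T = int sum_i (D_i / X_i) (sigma(X) dW)_i`` accumulated over the
    pre-explosion segment and ``predicted_error = -N_T / I_T``.  In the
    discrete scheme the identity ``rho_hat - rho = -N_T / I_T`` holds
    exactly (up to rounding) when ``rho`` is the rate used to simulate.
    """
    _full_resolution(traj)
    if traj.dW is None:
        raise ValueError("error decomposition requires stored Brownian increments")
    params = params or traj.params
    K, L = params.K, params.L
    m = _n_valid_states(traj)
    X = traj.X[: m - 1]
    N_T = 0.0
    for n in range(m - 1):
        D = linkage_disequilibrium(X[n], K, L)
        N_T += float((D / X[n]) @ sigma_pal_dot(X[n], traj.dW[n]))
    I = observed_information(traj, params)
    if I == 0.0:
        return N_T, 0.0
    return N_T, -N_T / I


def loglikelihood(pf: PathFunctionals, phi) -> float:
    """Convenience wrapper for ``pf.loglik(phi)``."""
    return pf.loglik(phi)
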