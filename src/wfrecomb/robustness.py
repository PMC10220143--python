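"""Robustness of path estimators to confounding drift components.

A nuisance contribution ``c(x)`` to the drift leaves the estimator of
``phi`` unchanged precisely when the weighted inner product

    R_k(x) = sum_i Z_ik(x) c_i(x) / x_i = 0    for every parameter k,

where ``Z_ik = d a_i / d phi_k`` is the score of the target problem.  This
module evaluates that condition numerically on random interior points of
the simplex, classifies the standard catalog of two-locus estimation
problems, and provides the selection-adjusted recombination estimator
whose correction term vanishes identically for non-epistatic selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np

from .params import ModelParams, Selection
from .model import drift_mutation, drift_recombination, drift_selection, marginals
from .functionals import Estimate, rho_hat, path_functionals
from .simulate import Trajectory

REL_ZERO = 1e-10  # relative threshold for declaring a numeric zero


@dataclass
class ConfoundingProblem:
    """A (target score, confounder drift) pair."""

    label: str
    Z_fn: Callable[[np.ndarray], np.ndarray]   # x -> (d, r)
    c_fn: Callable[[np.ndarray], np.ndarray]   # x -> (d,)
    description: str = ""


def robustness_condition(problem: ConfoundingProblem, x: np.ndarray) -> np.ndarray:
    """The r-vector ``R_k(x)``; the problem is robust at x iff all entries vanish."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("robustness condition requires an interior point")
    Z = np.atleast_2d(np.asarray(problem.Z_fn(x), dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    c = np.asarray(problem.c_fn(x), dtype=float)
    return (Z / x[:, None]).T @ c


def _is_robust_at(problem: ConfoundingProblem, x: np.ndarray,
                  rel_tol: float = REL_ZERO) -> bool:
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(problem.Z_fn(x), dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    c = np.asarray(problem.c_fn(x), dtype=float)
    terms = Z * (c / x)[:, None]
    R = terms.sum(axis=0)
    scale = np.abs(terms).sum(axis=0)
    return bool(np.all(np.abs(R) <= rel_tol * np.maximum(scale, 1e-300)))


# --------------------------------------------------------------- catalog
def _mutation_score_A(params: ModelParams) -> Callable[[np.ndarray], np.ndarray]:
    """Score for estimating theta_A: Z_ij = 1/2 [ (P_A' X)_ij - x_ij ]."""
    K, L = params.K, params.L
    PA = params.P_A

    def Z(x):
        X = x.reshape(K, L)
        return (0.5 * (PA.T @ X - X)).ravel()[:, None]

    return Z


def _genic_score_A(params: ModelParams) -> Callable[[np.ndarray], np.ndarray]:
    """Scores for genic selection at locus A: Z_ij,k = x_ij/2 (delta_ik - x_{k.})."""
    K, L = params.K, params.L

    def Z(x):
        p, _ = marginals(x, K, L)
        cols = []
        for k in range(K):
            delta = np.repeat(np.eye(K)[k], L)
            cols.append(0.5 * x * (delta - p[k]))
        return np.stack(cols, axis=1)

    return Z


def _recombination_score(params: ModelParams) -> Callable[[np.ndarray], np.ndarray]:
    K, L = params.K, params.L

    def Z(x):
        p, q = marginals(x, K, L)
        return (np.outer(p, q).ravel() - x)[:, None]

    return Z


def standard_catalog(
    params: Optional[ModelParams] = None,
    s_B: Optional[np.ndarray] = None,
    s_A: Optional[np.ndarray] = None,
    rho: float = 1.3,
) -> List[ConfoundingProblem]:
    """The catalog of two-locus confounding problems.

    Entries: the recombination-vs-selection and selection-vs-recombination
    robust pairs, then (i)-(vii): (i) mutation at A vs selection at B and
    (ii) genic selection at A vs mutation at B are robust; (iii)
    recombination vs mutation, (iv) mutation at A vs mutation at B, (v)
    mutation at A vs recombination, (vi) mutation at A vs selection at A,
    and (vii) genic selection at A vs mutation at A are not.
    """
    params = params or ModelParams(
        allele_counts=(2, 2), theta_A=1.0, theta_B=1.0)
    K, L = params.K, params.L
    if s_A is None:
        s_A = 0.7 + 0.3 * np.arange(K)
    if s_B is None:
        s_B = 0.5 + 0.4 * np.arange(L)
    sel_A = Selection(genic=np.asarray(s_A, dtype=float))
    sel_B_tensor = Selection(s_A=np.zeros((K, K)),
                             s_B=np.add.outer(s_B, s_B))

    mut_A = lambda x: drift_mutation(
        x, ModelParams(allele_counts=(K, L), theta_A=params.theta_A,
                       P_A=params.P_A, P_B=params.P_B))
    mut_B = lambda x: drift_mutation(
        x, ModelParams(allele_counts=(K, L), theta_B=params.theta_B,
                       P_A=params.P_A, P_B=params.P_B))
    recomb = lambda x: drift_recombination(x, rho, K, L)
    sel_at_A = lambda x: drift_selection(x, sel_A, K, L)
    sel_at_B = lambda x: drift_selection(x, sel_B_tensor, K, L)

    Zrho = _recombination_score(params)
    ZmutA = _mutation_score_A(params)
    ZselA = _genic_score_A(params)

    return [
        ConfoundingProblem("recombination_vs_selection_additive", Zrho,
                           lambda x: sel_at_A(x) + sel_at_B(x),
                           "rho estimation with non-epistatic selection"),
        ConfoundingProblem("selection_A_vs_recombination", ZselA, recomb,
                           "genic selection at A confounded by recombination"),
        ConfoundingProblem("(i) mutation_A_vs_selection_B", ZmutA, sel_at_B),
        ConfoundingProblem("(ii) selection_A_vs_mutation_B", ZselA, mut_B),
        ConfoundingProblem("(iii) recombination_vs_mutation", Zrho,
                           lambda x: mut_A(x) + mut_B(x)),
        ConfoundingProblem("(iv) mutation_A_vs_mutation_B", ZmutA, mut_B),
        ConfoundingProblem("(v) mutation_A_vs_recombination", ZmutA, recomb),
        ConfoundingProblem("(vi) mutation_A_vs_selection_A", ZmutA, sel_at_A),
        ConfoundingProblem("(vii) selection_A_vs_mutation_A", ZselA, mut_A),
    ]

# labels expected to satisfy the robustness condition everywhere
ROBUST_LABELS = {
    "recombination_vs_selection_additive",
    "selection_A_vs_recombination",
    "(i) mutation_A_vs_selection_B",
    "(ii) selection_A_vs_mutation_B",
}


def catalog_check(
    n_points: int = 200,
    seed: int = 0,
    params: Optional[ModelParams] = None,
    rel_tol: float = REL_ZERO,
) -> List[dict]:
    """Classify every catalog entry by numeric evaluation at random points.

    Points are drawn flat (Dirichlet(1)) on the interior of the simplex with
    a fixed seed.  A problem is declared robust only if the condition holds
    at every sampled point.
    """
    problems = standard_catalog(params)
    d = (params or ModelParams()).d
    rng = np.random.default_rng(seed)
    pts = rng.dirichlet(np.ones(d), size=n_points)
    pts = np.clip(pts, 1e-12, None)
    pts /= pts.sum(axis=1, keepdims=True)
    out = []
    for prob in problems:
        robust = all(_is_robust_at(prob, x, rel_tol) for x in pts)
        out.append({"label": prob.label, "robust": robust})
    return out


# ----------------------------------------- selection-adjusted rho estimator
def rho_hat_selection_adjusted(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    selection: Optional[Selection] = None,
) -> Estimate:
    """Recombination estimator adjusted for a declared selection model.

    ``rho_sel = rho_hat - (1/I_T) int sum_ij (X_{i.} X_{.j} - X_ij)
    sum_kl (s_{ij,kl}/2) X_kl dt``.  For non-epistatic (additive or genic)
    selection the integrand vanishes pointwise and the adjustment is zero:
    ignoring such selection does not bias the recombination estimator.
    """
    params = params or traj.params
    if selection is None:
        selection = params.selection
    K, L = params.K, params.L
    base = ModelParams(allele_counts=(K, L), theta_A=params.theta_A,
                       theta_B=params.theta_B, P_A=params.P_A, P_B=params.P_B,
                       rho=params.rho)
    pf = path_functionals(traj, base)
    raw = pf.Y / pf.I_T
    adjustment = 0.0
    if selection is not None:
        s = selection.as_tensor(K, L)
        from .functionals import _n_valid_states
        m = _n_valid_states(traj)
        X = traj.X[: m]
        dts = np.diff(traj.times[: m])
        for n in range(m - 1):
            x = X[n]
            p, q = marginals(x, K, L)
            negD = np.outer(p, q).ravel() - x
            adjustment += float(negD @ (0.5 * (s @ x))) * dts[n]
        adjustment /= pf.I_T
    value = raw - adjustment
    return Estimate(
        value=value, raw=raw, exploded=pf.exploded, I_T=pf.I_T,
        T_eff=pf.T_eff, S=pf.S)
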