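"""Drift components and diffusion matrix of the Wright-Fisher model.

All functions operate on stacked (flat, row-major) frequency vectors; see
:mod:`wfrecomb.params` for the stacking convention.  Every drift component
returned here sums to zero over haplotypes, the algebraic condition for the
diffusion to remain on the simplex.

The drift splits as ``mu(x; phi) = c(x) + a(x; phi)`` where ``a`` carries the
parameters to be estimated (and vanishes at the reference parameter) and
``c`` collects the nuisance processes treated as known — in the standard
setup mutation, optionally plus a confounding selection term.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams, Selection


def marginals(x: np.ndarray, K: int, L: int) -> Tuple[np.ndarray, np.ndarray]:
    """Allele-frequency marginals ``x_{i.}`` (length K) and ``x_{.j}`` (length L)."""
    x = np.asarray(x, dtype=float)
    if x.size != K * L:
        raise ValueError(f"dimension mismatch: len(x)={x.size} != K*L={K * L}")
    X = x.reshape(K, L)
    return X.sum(axis=1), X.sum(axis=0)


def linkage_disequilibrium(x: np.ndarray, K: int, L: int) -> np.ndarray:
    """Per-haplotype linkage disequilibrium ``D_ij = x_ij - x_{i.} x_{.j}``.

    The entries sum to zero; in the diallelic case all four share the same
    magnitude (the classical scalar ``D``).
    """
    x = np.asarray(x, dtype=float)
    p, q = marginals(x, K, L)
    return x - np.outer(p, q).ravel()


def drift_recombination(x: np.ndarray, rho: float, K: int, L: int) -> np.ndarray:
    """Recombination drift ``a_ij = rho (x_{i.} x_{.j} - x_ij) = -rho D_ij``.

    ``rho`` enters without the conventional factor of 1/2.  Negative ``rho``
    is accepted (useful for internal checks) though the parameter space is
    ``[0, inf)``.
    """
    return -float(rho) * linkage_disequilibrium(x, K, L)


def drift_mutation(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Mutation drift for the two-locus model.

    ``c_ij = theta_A/2 sum_k x_kj (P^A_ki - delta_ik)
           + theta_B/2 sum_l x_il (P^B_lj - delta_jl)``.
    """
    K, L = params.K, params.L
    X = np.asarray(x, dtype=float).reshape(K, L)
    cA = params.P_A.T @ X - X
    cB = X @ params.P_B - X
    return (0.5 * params.theta_A * cA + 0.5 * params.theta_B * cB).ravel()


def drift_selection(x: np.ndarray, selection: Selection, K: int, L: int) -> np.ndarray:
    """Selection drift in any of the three parameterizations.

    For the general diploid epistatic tensor,
    ``a_ij = x_ij/2 [ sum_kl s_{ij,kl} x_kl - sum_klmn s_{kl,mn} x_kl x_mn ]``;
    the genic form uses ``a_ij = x_ij/2 (s^A_i - sum_k s^A_k x_{k.})`` directly.
    """
    x = np.asarray(x, dtype=float)
    if selection.mode == "genic":
        p, _ = marginals(x, K, L)
        sA = selection.genic
        if sA.size != K:
            raise ValueError(f"genic selection vector must have length K={K}")
        sbar = float(sA @ p)
        return 0.5 * x * (np.repeat(sA, L) - sbar)
    s = selection.as_tensor(K, L)
    m = s @ x                      # marginal fitness of each haplotype
    mbar = float(x @ m)            # mean fitness
    return 0.5 * x * (m - mbar)


def diffusion_matrix(x: np.ndarray) -> np.ndarray:
    """Wright-Fisher diffusion matrix ``V_ij(x) = x_i (delta_ij - x_j)``.

    Symmetric, positive semidefinite, with zero row sums (rank <= d - 1).
    """
    x = np.asarray(x, dtype=float)
    return np.diag(x) - np.outer(x, x)


def vstar_inverse(x: np.ndarray) -> np.ndarray:
    """Closed-form inverse of the leading (d-1) x (d-1) block of ``V(x)``.

    ``[V*(x)^{-1}]_ij = 1/x_d + delta_ij / x_i``; requires every coordinate
    strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise np.linalg.LinAlgError(
            "V* is singular: a haplotype frequency is zero")
    head = x[:-1]
    return 1.0 / x[-1] + np.diag(1.0 / head)


def sigma_pal(x: np.ndarray) -> np.ndarray:
    """Symmetric square root ``sigma_ij = sqrt(x_i) (delta_ij - sqrt(x_i x_j))``.

    Satisfies ``sigma sigma^T = V(x)``, is bounded on the simplex (unlike the
    Cholesky factor, which blows up at the boundary), and uses d driving
    Brownian coordinates.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0):
        raise ValueError("frequencies must be non-negative")
    r = np.sqrt(x)
    return np.diag(r) - np.outer(x, r)


def sigma_pal_dot(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Matrix-free product ``sigma(x) @ w`` in O(d) flops.

    ``(sigma w)_i = sqrt(x_i) w_i - x_i * sum_j sqrt(x_j) w_j``.
    """
    r = np.sqrt(x)
    return r * w - x * float(r @ w)


def multilocus_marginals(
    x: np.ndarray, allele_counts: Sequence[int], j: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Prefix/suffix marginals at cut ``j`` (between locus j and j+1, 1-based).

    For each haplotype ``i = (i_1, ..., i_l)`` returns the pair
    ``(x_{i<=j}, x_{i>j})``: the marginal frequency of its first j alleles
    and of its last ``l - j`` alleles, each broadcast back to a length-d
    vector aligned with ``x``.
    """
    counts = tuple(int(k) for k in allele_counts)
    ell = len(counts)
    if not 1 <= j <= ell - 1:
        raise ValueError(f"cut index must be in [1, {ell - 1}], got {j}")
    X = np.asarray(x, dtype=float).reshape(counts)
    prefix = X.sum(axis=tuple(range(j, ell)), keepdims=True)
    suffix = X.sum(axis=tuple(range(0, j)), keepdims=True)
    ones = np.ones_like(X)
    return (prefix * ones).ravel(), (suffix * ones).ravel()


def drift_recombination_multilocus(
    x: np.ndarray, rho: Sequence[float], allele_counts: Sequence[int]
) -> np.ndarray:
    """Multi-locus recombination drift
    ``a_i = sum_j rho_j (x_{i<=j} x_{i>j} - x_i)``.

    Reduces to :func:`drift_recombination` for two loci.
    """
    x = np.asarray(x, dtype=float)
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    ell = len(allele_counts)
    if rho.size != ell - 1:
        raise ValueError(f"need {ell - 1} rates, got {rho.size}")
    a = np.zeros_like(x)
    for j in range(1, ell):
        pre, suf = multilocus_marginals(x, allele_counts, j)
        a += rho[j - 1] * (pre * suf - x)
    return a


def total_drift(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Full drift ``mu(x) = c(x) + a(x)``: mutation + recombination (+ selection)."""
    if params.num_loci == 2:
        mu = drift_mutation(x, params) + drift_recombination(
            x, params.rho, params.K, params.L)
        if params.selection is not None:
            mu = mu + drift_selection(x, params.selection, params.K, params.L)
        return mu
    return drift_recombination_multilocus(x, params.rho, params.allele_counts)


def nuisance_drift(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """The 'known' drift component c(x) used to compensate the path.

    Mutation, plus the selection term when the model declares selection as a
    nuisance (the default interpretation for recombination estimation).
    """
    if params.num_loci != 2:
        return np.zeros(np.asarray(x).size)
    c = drift_mutation(x, params)
    if params.selection is not None:
        c = c + drift_selection(x, params.selection, params.K, params.L)
    return c
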