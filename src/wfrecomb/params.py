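"""Model parameterization for the multi-locus Wright-Fisher diffusion.

The state of the population is a vector of haplotype frequencies on the
simplex ``Delta_{d-1}``, with ``d`` the product of the per-locus allele
counts.  Haplotypes are stacked in row-major (lexicographic) order: for two
loci with K and L alleles, haplotype ``(i, j)`` (1-based) maps to flat index
``(i - 1) * L + (j - 1)`` (0-based), i.e. ``numpy.reshape(x, (K, L))``
recovers the K x L frequency table.  For ``l`` loci the order is
lexicographic in ``(i_1, ..., i_l)``.

Timescale conventions
---------------------
The recombination rate ``rho`` enters the drift *without* a factor of 1/2:
``a_ij(x; rho) = rho * (x_{i.} x_{.j} - x_ij)``.  Mutation occurs at rate
``theta/2`` per locus and selection coefficients carry their conventional
factor of 1/2.  These conventions are fixed package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Optional, Sequence

import numpy as np
import yaml

SIMPLEX_TOL = 1e-9


def validate_frequencies(
    x: Sequence[float] | np.ndarray,
    d: Optional[int] = None,
    *,
    tol: float = SIMPLEX_TOL,
    interior: bool = False,
) -> np.ndarray:
    """Validate a stacked haplotype-frequency vector.

    Parameters
    ----------
    x : array-like
        Candidate frequency vector.
    d : int, optional
        Expected dimension.  A mismatch raises ``ValueError``.
    tol : float
        Tolerance on the simplex constraint ``sum(x) == 1``.
    interior : bool
        If True, additionally require every entry to be strictly positive.

    Returns
    -------
    numpy.ndarray
        The input as a float array (not renormalized; validation only).
    """
    x = np.asarray(x, dtype=float).ravel()
    if d is not None and x.size != d:
        raise ValueError(f"expected frequency vector of length {d}, got {x.size}")
    if np.any(x < -tol):
        raise ValueError("haplotype frequencies must be non-negative")
    if abs(x.sum() - 1.0) > tol:
        raise ValueError(f"frequencies must sum to 1 (got {x.sum():.12g})")
    if interior and np.any(x <= 0.0):
        raise ValueError("frequency vector must lie in the interior of the simplex")
    return x


def _check_stochastic(P: np.ndarray, name: str, tol: float = SIMPLEX_TOL) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if np.any(P < -tol):
        raise ValueError(f"{name} must have non-negative entries")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > tol:
        raise ValueError(f"rows of {name} must sum to 1")
    return P


@dataclass
class Selection:
    """One of three selection parameterizations for the two-locus model.

    ``epistatic`` is a dense d x d tensor ``s[ij, kl]`` of diploid selective
    advantages indexed by ordered haplotype pairs; ``additive`` is the
    non-epistatic special case ``s[ij, kl] = s_A[i, k] + s_B[j, l]``; and
    ``genic`` is a per-allele vector at locus A with drift
    ``x_ij / 2 * (s_A[i] - sum_k s_A[k] x_{k.})``.

    Exactly one parameterization may be supplied.
    """

    epistatic: Optional[np.ndarray] = None
    s_A: Optional[np.ndarray] = None
    s_B: Optional[np.ndarray] = None
    genic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        modes = [self.epistatic is not None,
                 (self.s_A is not None or self.s_B is not None),
                 self.genic is not None]
        if sum(modes) != 1:
            raise ValueError(
                "supply exactly one of: epistatic tensor, additive (s_A, s_B), "
                "or genic vector")
        for name in ("epistatic", "s_A", "s_B", "genic"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def mode(self) -> str:
        if self.epistatic is not None:
            return "epistatic"
        if self.genic is not None:
            return "genic"
        return "additive"

    def as_tensor(self, K: int, L: int) -> np.ndarray:
        """Return the dense d x d tensor ``s[ij, kl]`` on flat indices."""
        d = K * L
        if self.epistatic is not None:
            s = np.asarray(self.epistatic, dtype=float)
            if s.shape != (d, d):
                raise ValueError(f"epistatic tensor must be {d} x {d}")
            return s
        if self.genic is not None:
            # genic selection at locus A: s[ij,kl] = s_A[i] + s_A[k] would be
            # the diploid additive form; the haplotype-level advantage used in
            # the drift is s_A[i], i.e. s[ij,kl] = s_A[i] + s_A[k] up to a
            # constant that cancels in the drift.  We return s_A[i] + s_A[k].
            sA = np.zeros((K, K))
            sA += self.genic[:, None]
            sA += self.genic[None, :]
            sB = np.zeros((L, L))
            return _additive_tensor(sA, sB, K, L)
        sA = self.s_A if self.s_A is not None else np.zeros((K, K))
        sB = self.s_B if self.s_B is not None else np.zeros((L, L))
        return _additive_tensor(np.asarray(sA), np.asarray(sB), K, L)

    def is_symmetric(self, K: int, L: int, tol: float = 1e-12) -> bool:
        s = self.as_tensor(K, L)
        return bool(np.max(np.abs(s - s.T)) <= tol)


def _additive_tensor(sA: np.ndarray, sB: np.ndarray, K: int, L: int) -> np.ndarray:
    d = K * L
    s = np.zeros((d, d))
    for i in range(K):
        for j in range(L):
            for k in range(K):
                for l in range(L):
                    s[i * L + j, k * L + l] = sA[i, k] + sB[j, l]
    return s


@dataclass
class ModelParams:
    """Full drift specification for the Wright-Fisher diffusion.

    Parameters
    ----------
    allele_counts : tuple of int
        ``(K_1, ..., K_l)`` with each ``K_j >= 2``; two-locus aliases ``K``
        and ``L`` are available as properties.
    theta_A, theta_B : float
        Scaled mutation rates (mutation occurs at rate ``theta/2`` on the
        diffusion timescale).  Only meaningful for two loci.
    P_A, P_B : ndarray
        Row-stochastic mutation transition matrices (K x K and L x L).
        Default: parent-independent symmetric (all entries equal).
    rho : float or ndarray
        Recombination rate (scalar for two loci, omitting the conventional
        factor of 1/2) or vector ``(rho_1, ..., rho_{l-1})`` of inter-locus
        rates for ``l > 2``.
    selection : Selection, optional
        Optional selection component of the drift.
    """

    allele_counts: tuple = (2, 2)
    theta_A: float = 0.0
    theta_B: float = 0.0
    P_A: Optional[np.ndarray] = None
    P_B: Optional[np.ndarray] = None
    rho: float | np.ndarray = 0.0
    selection: Optional[Selection] = None

    def __post_init__(self) -> None:
        self.allele_counts = tuple(int(k) for k in self.allele_counts)
        if len(self.allele_counts) < 2 or any(k < 2 for k in self.allele_counts):
            raise ValueError("need at least two loci with >= 2 alleles each")
        if self.theta_A < 0 or self.theta_B < 0:
            raise ValueError("mutation rates must be non-negative")
        rho = np.asarray(self.rho, dtype=float)
        if np.any(rho < 0):
            raise ValueError("recombination rate(s) must lie in [0, inf)")
        if self.num_loci == 2:
            if rho.ndim > 0 and rho.size != 1:
                raise ValueError("two-locus model takes a scalar rho")
            self.rho = float(rho)
            K, L = self.allele_counts
            if self.P_A is None:
                self.P_A = np.full((K, K), 1.0 / K)
            if self.P_B is None:
                self.P_B = np.full((L, L), 1.0 / L)
            self.P_A = _check_stochastic(self.P_A, "P_A")
            self.P_B = _check_stochastic(self.P_B, "P_B")
            if self.P_A.shape[0] != K or self.P_B.shape[0] != L:
                raise ValueError("mutation matrix dimensions must match allele counts")
        else:
            if (self.theta_A or self.theta_B) and self.num_loci > 2:
                raise ValueError(
                    "mutation is only modelled for two loci; set theta_A = theta_B = 0")
            rho = np.atleast_1d(rho)
            if rho.size == 1:
                rho = np.full(self.num_loci - 1, float(rho[0]))
            if rho.size != self.num_loci - 1:
                raise ValueError(
                    f"need {self.num_loci - 1} inter-locus recombination rates")
            self.rho = rho
        if self.selection is not None and self.num_loci != 2:
            raise ValueError("selection is only modelled for two loci")

    # --- aliases -----------------------------------------------------------
    @property
    def num_loci(self) -> int:
        return len(self.allele_counts)

    @property
    def K(self) -> int:
        return self.allele_counts[0]

    @property
    def L(self) -> int:
        return self.allele_counts[1]

    @property
    def d(self) -> int:
        return prod(self.allele_counts)

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "allele_counts": list(self.allele_counts),
            "theta_A": float(self.theta_A),
            "theta_B": float(self.theta_B),
            "rho": (float(self.rho) if np.ndim(self.rho) == 0
                    else [float(r) for r in np.atleast_1d(self.rho)]),
        }
        if self.num_loci == 2:
            out["P_A"] = np.asarray(self.P_A).tolist()
            out["P_B"] = np.asarray(self.P_B).tolist()
        if self.selection is not None:
            sel = {}
            for name in ("epistatic", "s_A", "s_B", "genic"):
                v = getattr(self.selection, name)
                if v is not None:
                    sel[name] = np.asarray(v).tolist()
            out["selection"] = sel
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        data = dict(data)
        sel = data.pop("selection", None)
        selection = Selection(**sel) if sel else None
        return cls(selection=selection, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
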