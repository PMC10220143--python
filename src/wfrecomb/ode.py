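"""Deterministic (noise-free) recombination dynamics.

With mutation switched off, the two-locus deterministic system
``dx_ij/dt = rho (x_{i.} x_{.j} - x_ij)`` preserves the allele-frequency
marginals and relaxes exponentially to linkage equilibrium:

    x_ij(t) = x_ij(0) e^{-rho t} + x_{i.}(0) x_{.j}(0) (1 - e^{-rho t}).

Along this trajectory the accumulated information admits a closed form,

    I_T = rho^{-1} sum_ij x_{i.}(0) x_{.j}(0) log(x_ij(T) / x_ij(0)),

which stays finite as T -> infinity.  These closed forms serve as analytic
oracles for the stochastic-integral code: the path estimator evaluated on a
gridded deterministic trajectory must return the true rate up to O(dt).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams, validate_frequencies
from .model import marginals, total_drift


def ode_solution(x0: np.ndarray, rho: float, t, K: int = 2, L: int = 2) -> np.ndarray:
    """Deterministic trajectory at time(s) ``t`` (theta_A = theta_B = 0).

    Returns a length-d vector for scalar ``t`` or an ``(len(t), d)`` array.
    """
    x0 = validate_frequencies(x0, K * L)
    p, q = marginals(x0, K, L)
    eq = np.outer(p, q).ravel()
    t = np.asarray(t, dtype=float)
    decay = np.exp(-rho * t)
    if t.ndim == 0:
        return x0 * decay + eq * (1.0 - decay)
    return x0[None, :] * decay[:, None] + eq[None, :] * (1.0 - decay[:, None])


def info_closed_form(
    x0: np.ndarray, rho: float, T: float, K: int = 2, L: int = 2
) -> float:
    """Closed-form deterministic information ``I_T`` (requires rho > 0).

    ``T = inf`` returns the limit
    ``rho^{-1} sum_ij x_{i.}(0) x_{.j}(0) log(x_{i.}(0) x_{.j}(0) / x_ij(0))``.
    """
    if rho <= 0:
        raise ValueError("closed-form information requires rho > 0")
    x0 = validate_frequencies(x0, K * L, interior=True)
    p, q = marginals(x0, K, L)
    eq = np.outer(p, q).ravel()
    if np.isinf(T):
        return float(np.sum(eq * np.log(eq / x0)) / rho)
    xT = ode_solution(x0, rho, T, K, L)
    return float(np.sum(eq * np.log(xT / x0)) / rho)


def estimator_on_deterministic_path(
    x0: np.ndarray, rho: float, T: float, dt: float, K: int = 2, L: int = 2
) -> float:
    """Raw path estimator evaluated on the gridded deterministic trajectory.

    Builds the exact solution on a grid of spacing ``dt``, applies the
    left-point Riemann rules of the stochastic estimator (with c = 0), and
    returns the resulting rate.  Converges to ``rho`` at order O(dt); for
    ``rho = 0`` the numerator vanishes identically and 0 is returned.
    """
    from .functionals import path_functionals
    from .simulate import Trajectory

    if rho < 0:
        raise ValueError("rho must be non-negative")
    n = int(round(T / dt))
    times = np.arange(n + 1) * dt
    X = ode_solution(x0, rho, times, K, L)
    params = ModelParams(allele_counts=(K, L), rho=rho)
    traj = Trajectory(times=times, X=X, params=params, dt=dt)
    pf = path_functionals(traj, params)
    if rho == 0.0:
        return 0.0
    if pf.I_T <= 1e-18:
        raise ValueError("path carries no information (equilibrium start)")
    return pf.Y / pf.I_T


def deterministic_path_numeric(
    params: ModelParams,
    x0: np.ndarray,
    T: float,
    n_eval: int = 1001,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Numerically integrated deterministic system ``dx/dt = c(x) + a(x)``.

    Covers regimes without a closed form here (mutation present, or more
    than two loci).  Returns ``(times, X)`` with ``X`` of shape
    ``(n_eval, d)``.
    """
    x0 = validate_frequencies(x0, params.d, interior=True)
    times = np.linspace(0.0, T, n_eval)
    sol = solve_ivp(
        lambda _, x: total_drift(x, params),
        (0.0, T),
        x0,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:       # pragma: no cover - defensive
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return times, sol.y.T
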