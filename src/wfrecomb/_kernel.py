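"""Streaming Euler-Maruyama kernel for replicate batches (numba-compiled).

Simulates the two-locus diffusion and accumulates the score Y and the
observed information I on the fly at full step resolution, so replicate
batches at small step sizes never materialize their paths.  Accumulation
uses the same left-point rules as :mod:`wfrecomb.functionals` and stops at
the last all-positive grid point when a coordinate is clipped (the
explosion event); the replicate loop then moves on, since estimators only
consume the pre-explosion segment.

The kernel is cross-checked against the reference numpy simulator and
functionals by injecting a common array of Brownian increments.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_replicates(
    x0, K, L, theta_A, theta_B, PA, PB, rho, dt, n_steps, seeds, noise, use_noise
):
    """Simulate ``len(seeds)`` replicates; return per-replicate summaries.

    Output array has one row (Y, I, exploded, S) per replicate, with Y and
    I accumulated over the pre-explosion segment, ``exploded`` a 0/1 flag
    and S the explosion time (nan if none).  ``noise`` (n_rep, n_steps, d)
    holds pre-scaled Brownian increments and is only read when
    ``use_noise`` is true; otherwise each replicate draws from numba's
    global RNG seeded with its entry of ``seeds``.
    """
    n_rep = len(seeds)
    d = K * L
    out = np.empty((n_rep, 4))
    sq = np.sqrt(dt)
    for r in range(n_rep):
        if not use_noise:
            np.random.seed(seeds[r])
        x = x0.copy()
        xnew = np.empty(d)
        z = np.empty(d)
        c = np.empty(d)
        p = np.empty(K)
        q = np.empty(L)
        Y = 0.0
        I = 0.0
        exploded = False
        S = np.nan
        for step in range(n_steps):
            for i in range(K):
                p[i] = 0.0
            for j in range(L):
                q[j] = 0.0
            for i in range(K):
                for j in range(L):
                    xi = x[i * L + j]
                    p[i] += xi
                    q[j] += xi
            # mutation drift
            for i in range(K):
                for j in range(L):
                    sA = 0.0
                    for k in range(K):
                        sA += x[k * L + j] * PA[k, i]
                    sB = 0.0
                    for l in range(L):
                        sB += x[i * L + l] * PB[l, j]
                    xi = x[i * L + j]
                    c[i * L + j] = (0.5 * theta_A * (sA - xi)
                                    + 0.5 * theta_B * (sB - xi))
            # information integrand at the left point
            g = 0.0
            for i in range(K):
                for j in range(L):
                    xi = x[i * L + j]
                    D = xi - p[i] * q[j]
                    g += D * D / xi
            # noise and proposed state
            dot = 0.0
            for i in range(d):
                if use_noise:
                    z[i] = noise[r, step, i]
                else:
                    z[i] = np.random.standard_normal() * sq
                dot += np.sqrt(x[i]) * z[i]
            clipped = False
            for i in range(K):
                for j in range(L):
                    ij = i * L + j
                    a = rho * (p[i] * q[j] - x[ij])
                    sdw = np.sqrt(x[ij]) * z[ij] - x[ij] * dot
                    xnew[ij] = x[ij] + (c[ij] + a) * dt + sdw
                    if xnew[ij] <= 0.0:
                        clipped = True
            if clipped:
                exploded = True
                S = (step + 1) * dt
                break
            for i in range(K):
                for j in range(L):
                    ij = i * L + j
                    dxt = xnew[ij] - x[ij] - c[ij] * dt
                    Y += (p[i] * q[j] / x[ij]) * dxt
            I += g * dt
            for i in range(d):
                x[i] = xnew[i]
        out[r, 0] = Y
        out[r, 1] = I
        out[r, 2] = 1.0 if exploded else 0.0
        out[r, 3] = S
    return out


_EMPTY_NOISE = np.zeros((1, 1, 1))


def run_replicates(
    x0,
    K: int,
    L: int,
    theta_A: float,
    theta_B: float,
    PA,
    PB,
    rho: float,
    dt: float,
    n_steps: int,
    seeds=None,
    noise=None,
):
    """Python wrapper validating arguments and dispatching to the kernel."""
    x0 = np.ascontiguousarray(x0, dtype=np.float64)
    PA = np.ascontiguousarray(PA, dtype=np.float64)
    PB = np.ascontiguousarray(PB, dtype=np.float64)
    if noise is not None:
        noise = np.ascontiguousarray(noise, dtype=np.float64)
        seeds = np.zeros(noise.shape[0], dtype=np.int64)
        return simulate_replicates(
            x0, K, L, theta_A, theta_B, PA, PB, rho, dt, n_steps,
            seeds, noise, True)
    seeds = np.ascontiguousarray(seeds, dtype=np.int64)
    return simulate_replicates(
        x0, K, L, theta_A, theta_B, PA, PB, rho, dt, n_steps,
        seeds, _EMPTY_NOISE, False)
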