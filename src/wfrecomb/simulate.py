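"""Euler-Maruyama simulation of the Wright-Fisher SDE.

The update rule is

    X(t + dt) = X(t) + [c(X(t)) + a(X(t))] dt + sigma(X(t)) dW(t),

with ``sigma`` the bounded symmetric square root of the Wright-Fisher
covariance (d driving Brownian coordinates).  If any coordinate of the
proposed state is <= 0 the coordinate is clipped to zero, the state is
renormalized onto the simplex, and the event is recorded as an *explosion*:
the discrete proxy for the accumulated information becoming infinite.
Simulation continues to the horizon (the post-explosion segment is useful
for diagnostics) but estimators consume only the pre-explosion segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .params import ModelParams, validate_frequencies
from .model import total_drift, sigma_pal_dot


@dataclass
class SimConfig:
    """Simulation settings.

    ``dt``/``T`` default to the values of the reference simulation study
    (1e-6 and 1).  ``thin_stride`` thins *storage only*; when functionals
    must be accumulated at full resolution, simulate with stride 1 or use
    the streaming experiment kernel.  ``boundary_floor`` is the clipping
    threshold for explosion detection (exactly 0 by default; an epsilon
    floor is exposed but not the model's convention).
    """

    dt: float = 1e-6
    T: float = 1.0
    seed: Optional[int] = None
    store_brownian: bool = False
    thin_stride: int = 1
    boundary_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T <= self.dt:
            raise ValueError("horizon T must exceed dt")
        if self.thin_stride < 1:
            raise ValueError("thin_stride must be >= 1")


@dataclass
class Trajectory:
    """A gridded haplotype-frequency path.

    ``times`` has shape (N+1,), ``X`` shape (N+1, d).  ``dW`` optionally
    stores the Brownian increments (N, d) at the stored resolution.
    ``explosion_step`` is the index (into ``times``) of the first clipped
    grid point and ``explosion_time`` the corresponding time S; both are
    None when the path stayed interior.
    """

    times: np.ndarray
    X: np.ndarray
    params: Optional[ModelParams] = None
    dt: Optional[float] = None
    dW: Optional[np.ndarray] = None
    explosion_step: Optional[int] = None
    explosion_time: Optional[float] = None
    seed: Optional[int] = None
    thin_stride: int = 1

    @property
    def exploded(self) -> bool:
        return self.explosion_step is not None

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def pre_explosion_length(self) -> int:
        """Number of stored grid points with all coordinates strictly positive."""
        if self.explosion_step is None:
            return len(self.times)
        return self.explosion_step

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write the path as plain CSV plus a YAML metadata sidecar.

        Header is ``time,x_1,...,x_d``; floats at full precision so the
        round trip is lossless.
        """
        path = Path(path)
        cols = {"time": self.times}
        for i in range(self.d):
            cols[f"x_{i + 1}"] = self.X[:, i]
        # default float formatting is the shortest round-trip repr: lossless
        pd.DataFrame(cols).to_csv(path, index=False)
        meta = {
            "dt": self.dt,
            "seed": self.seed,
            "thin_stride": self.thin_stride,
            "explosion_step": self.explosion_step,
            "explosion_time": self.explosion_time,
        }
        if self.params is not None:
            meta["params"] = self.params.to_dict()
        with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        times = df["time"].to_numpy()
        X = df[[c for c in df.columns if c != "time"]].to_numpy()
        meta_path = path.with_suffix(path.suffix + ".meta.yaml")
        meta = {}
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = yaml.safe_load(fh) or {}
        params = meta.get("params")
        return cls(
            times=times,
            X=X,
            params=ModelParams.from_dict(params) if params else None,
            dt=meta.get("dt"),
            explosion_step=meta.get("explosion_step"),
            explosion_time=meta.get("explosion_time"),
            seed=meta.get("seed"),
            thin_stride=meta.get("thin_stride", 1),
        )


def euler_maruyama(
    params: ModelParams,
    x0,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[np.ndarray] = None,
) -> Trajectory:
    """Simulate one path of the Wright-Fisher SDE.

    Parameters
    ----------
    params : ModelParams
        Drift specification (mutation, recombination, optional selection).
    x0 : array-like
        Initial frequencies, strictly interior.
    config : SimConfig
        Step size, horizon, seed, storage options.
    rng : numpy.random.Generator, optional
        Overrides ``config.seed``.
    noise : ndarray (N, d), optional
        Pre-specified Brownian increments (already scaled by sqrt(dt)).
        Supplying zeros yields the deterministic Euler trajectory; supplying
        the ``dW`` stored from a previous run replays it exactly.

    Returns
    -------
    Trajectory
    """
    d = params.d
    x0 = validate_frequencies(x0, d, interior=True)
    n_steps = int(round(config.T / config.dt))
    dt = config.dt
    sq = np.sqrt(dt)
    if noise is None and rng is None:
        rng = np.random.default_rng(config.seed)

    stride = config.thin_stride
    n_stored = n_steps // stride + 1
    X = np.empty((n_stored, d))
    times = np.empty(n_stored)
    store_dW = config.store_brownian and stride == 1
    dW = np.empty((n_steps, d)) if store_dW else None

    x = x0.copy()
    X[0] = x
    times[0] = 0.0
    explosion_step_full: Optional[int] = None
    floor = config.boundary_floor
    k = 1
    for n in range(n_steps):
        if noise is not None:
            dw = noise[n]
        else:
            dw = rng.standard_normal(d) * sq
        if store_dW:
            dW[n] = dw
        x = x + total_drift(x, params) * dt + sigma_pal_dot(x, dw)
        if np.any(x <= floor):
            if explosion_step_full is None:
                explosion_step_full = n + 1
            x = np.where(x <= floor, 0.0, x)
            x = x / x.sum()
        if (n + 1) % stride == 0:
            X[k] = x
            times[k] = (n + 1) * dt
            k += 1
    X = X[:k]
    times = times[:k]

    explosion_step = None
    explosion_time = None
    if explosion_step_full is not None:
        explosion_time = explosion_step_full * dt
        # index of first stored grid point at or after the explosion
        explosion_step = int(np.searchsorted(times, explosion_time - 1e-15))
    return Trajectory(
        times=times,
        X=X,
        params=params,
        dt=dt,
        dW=dW,
        explosion_step=explosion_step,
        explosion_time=explosion_time,
        seed=config.seed,
        thin_stride=stride,
    )


def batch_simulate(
    params: ModelParams, x0, config: SimConfig, n_replicates: int
) -> List[Trajectory]:
    """Simulate independent replicates on reproducible substreams.

    Replicate r draws its generator from child r of
    ``SeedSequence(config.seed)``, so any replicate can be regenerated in
    isolation and replicates are exchangeable.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        out.append(euler_maruyama(params, x0, config, rng=rng))
    return out
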