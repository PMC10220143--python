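"""Likelihood-ratio test for the presence of recombination.

The null value ``rho_0 = 0`` sits on the boundary of the parameter space
``[0, inf)``, so the likelihood-ratio statistic ``Lambda = rho_hat^2 I_T``
is asymptotically distributed as an equal mixture of a point mass at zero
(chi-square with 0 df) and a chi-square with 1 df under the null.  The
level-alpha test therefore rejects when ``Lambda`` exceeds the
``(1 - alpha)`` quantile of that mixture — equivalently the
``(1 - 2 alpha)`` quantile of a chi-square(1).

When the information has exploded the statistic is defined piecewise:
``+inf`` if the corrected estimate is positive (certain rejection), 0 if it
is zero.  The exact null in the explosion regime is unknown; retaining the
mixture threshold is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import chi2

from .functionals import Estimate, PathFunctionals


@dataclass
class TestResult:
    lam: float
    threshold: float
    reject: bool
    level: float


def lrt_statistic(est: Estimate, pf: Optional[PathFunctionals] = None) -> float:
    """Lambda = rho_hat_MLE^2 * I_T, with the piecewise explosion convention."""
    value = float(np.atleast_1d(est.value)[0]) if np.ndim(est.value) else float(est.value)
    if est.exploded:
        return np.inf if value > 0 else 0.0
    I_T = float(pf.I_T) if pf is not None else float(est.I_T)
    return value * value * I_T


def mixture_quantile(level: float) -> float:
    """Quantile of the equal chi2_0 / chi2_1 mixture.

    ``F_m(x) = 1/2 + 1/2 F_{chi2_1}(x)`` for x >= 0, so
    ``F_m^{-1}(p) = F_{chi2_1}^{-1}(2p - 1)``; only defined for p > 1/2
    because of the atom at zero.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("mixture quantile defined for levels in (0.5, 1)")
    return float(chi2.ppf(2.0 * level - 1.0, df=1))


def mixture_cdf(x: float) -> float:
    if x < 0:
        return 0.0
    return 0.5 + 0.5 * float(chi2.cdf(x, df=1))


def reject_null(lam: float, level: float = 0.05) -> bool:
    """Reject rho_0 = 0 at the given size (default 5%)."""
    return bool(lam > mixture_quantile(1.0 - level))


def test_recombination(
    est: Estimate, pf: Optional[PathFunctionals] = None, level: float = 0.05
) -> TestResult:
    lam = lrt_statistic(est, pf)
    thr = mixture_quantile(1.0 - level)
    return TestResult(lam=lam, threshold=thr, reject=bool(lam > thr), level=level)
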