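"""Multivariate-normal rectangle probabilities.

Thin wrapper over :func:`scipy.stats.multivariate_normal.cdf` (Genz
quasi-Monte-Carlo integration) adding closed-form short-circuits in
dimension one, an absolute-tolerance knob, and a fixed seed for the
randomised part of the algorithm so results are reproducible per run
configuration.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

__all__ = ["rectangle_probability", "DEFAULT_TOL", "DEFAULT_SEED"]

DEFAULT_TOL = 1e-6
DEFAULT_SEED = 20190521


def rectangle_probability(
    mean: np.ndarray,
    cov: np.ndarray,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    *,
    tol: float = DEFAULT_TOL,
    seed: int = DEFAULT_SEED,
) -> float:
    """P(lower <= X <= upper) for X ~ N(mean, cov).

    ``lower`` / ``upper`` default to -inf / +inf; entries may be infinite.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    m = mean.shape[0]
    lower = np.full(m, -np.inf) if lower is None else np.asarray(lower, dtype=float)
    upper = np.full(m, np.inf) if upper is None else np.asarray(upper, dtype=float)
    if np.any(upper <= lower):
        return 0.0
    if m == 1:
        sd = float(np.sqrt(np.atleast_2d(cov)[0, 0]))
        return float(norm.cdf(upper[0], mean[0], sd) - norm.cdf(lower[0], mean[0], sd))
    p = multivariate_normal.cdf(
        upper,
        mean=mean,
        cov=np.atleast_2d(cov),
        lower_limit=lower,
        abseps=tol,
        rng=np.random.default_rng(seed),
    )
    return float(min(1.0, max(0.0, p)))
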