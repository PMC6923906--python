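"""Beta-Poisson model: X ~ Poisson(scale * p), p ~ Beta(alpha, beta).

The pmf/CDF integrate the Poisson over the Beta mixing density with
Gauss-Jacobi quadrature (weight (1-t)^(beta-1) * t^(alpha-1)); the fitter
is a numeric MLE over (log alpha, log beta, log scale).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln, logsumexp, roots_jacobi

from ._base import ModelParams

QUADRATURE_ORDER = 50


@lru_cache(maxsize=256)
def _nodes(alpha: float, beta: float, order: int):
    # Jacobi weight (1-u)^a (1+u)^b on [-1,1]; mapped to t=(1+u)/2 on [0,1]
    u, w = roots_jacobi(order, beta - 1.0, alpha - 1.0)
    t = (1.0 + u) / 2.0
    logconst = -betaln(alpha, beta) - (alpha + beta - 1.0) * np.log(2.0)
    return t, np.log(w), logconst


def bp_logpmf(x, alpha, beta, scale, order: int = QUADRATURE_ORDER):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t, logw, logconst = _nodes(float(alpha), float(beta), order)
    comp = logw[None, :] + stats.poisson.logpmf(x[:, None], scale * t[None, :])
    return logsumexp(comp, axis=1) + logconst


def bp_cdf(q, alpha, beta, scale, order: int = QUADRATURE_ORDER):
    q = np.atleast_1d(np.asarray(q, dtype=float))
    t, logw, logconst = _nodes(float(alpha), float(beta), order)
    with np.errstate(divide="ignore"):
        comp = logw[None, :] + stats.poisson.logcdf(q[:, None], scale * t[None, :])
    out = np.exp(logsumexp(comp, axis=1) + logconst)
    return np.clip(out, 0.0, 1.0)


def bp_loglik(x, alpha, beta, scale) -> float:
    return float(bp_logpmf(x, alpha, beta, scale).sum())


def fit_bp(x: np.ndarray) -> tuple[ModelParams, float, bool]:
    m = max(float(np.mean(x)), 1e-8)
    vals, counts = np.unique(np.asarray(x, dtype=float), return_counts=True)

    def negll(theta):
        a, b, s = np.exp(theta)
        if not (1e-3 < a < 1e3 and 1e-3 < b < 1e3 and 1e-3 < s < 1e7):
            return 1e12
        return -float(counts @ bp_logpmf(vals, a, b, s))

    starts = []
    for a0, b0 in ((0.5, 0.5), (0.5, 2.0), (1.0, 1.0), (2.0, 4.0)):
        s0 = m * (a0 + b0) / a0
        starts.append(np.log([a0, b0, max(s0, 1e-6)]))
    start = min(starts, key=negll)
    best = optimize.minimize(
        negll, start, method="Nelder-Mead",
        options={"maxiter": 800, "xatol": 1e-6, "fatol": 1e-8},
    )
    a, b, s = np.exp(best.x)
    params = ModelParams(bp_alpha=float(a), bp_beta=float(b), bp_scale=float(s))
    return params, float(-best.fun), bool(best.success)


def sample_bp(alpha, beta, scale, n, rng: np.random.Generator) -> np.ndarray:
    p = rng.beta(alpha, beta, size=n)
    return rng.poisson(scale * p).astype(float)
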