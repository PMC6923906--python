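"""Fitters for the count-valued models: P, NB, ZIP, ZINB."""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from ._base import ModelParams

_RATE_FLOOR = 1e-8


def fit_poisson(x: np.ndarray) -> tuple[ModelParams, float]:
    lam = max(float(np.mean(x)), _RATE_FLOOR)
    ll = float(stats.poisson.logpmf(x, lam).sum())
    return ModelParams(lambda_=lam), ll


def _nb_profile_negll(log_size: float, x: np.ndarray) -> float:
    size = np.exp(log_size)
    prob = size / (size + x.mean())
    return -float(stats.nbinom.logpmf(x, size, prob).sum())


def fit_nb(x: np.ndarray) -> tuple[ModelParams, float]:
    """NB MLE via the profile likelihood in the size parameter.

    Given size r the success probability has the closed form
    p = r / (r + mean); r is optimised numerically on the log scale.
    Equidispersed data drives r to the upper bound (Poisson limit).
    """
    m = x.mean()
    if m <= 0:
        size = 1e4
    else:
        res = optimize.minimize_scalar(
            _nb_profile_negll, args=(x,), bounds=(np.log(1e-3), np.log(1e6)),
            method="bounded", options={"xatol": 1e-8},
        )
        size = float(np.exp(res.x))
    prob = size / (size + max(m, _RATE_FLOOR))
    ll = float(stats.nbinom.logpmf(x, size, prob).sum())
    return ModelParams(nb_size=size, nb_prob=prob), ll


def zip_loglik(x: np.ndarray, pi0: float, lam: float) -> float:
    zero = x == 0
    n0 = int(zero.sum())
    ll = 0.0
    if n0:
        ll += n0 * np.logaddexp(
            np.log(max(pi0, 1e-300)), np.log1p(-min(pi0, 1 - 1e-16)) - lam
        )
    nz = x[~zero]
    if nz.size:
        ll += np.log1p(-min(pi0, 1 - 1e-16)) * nz.size
        ll += float(stats.poisson.logpmf(nz, lam).sum())
    return float(ll)


def fit_zip(x: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> tuple[ModelParams, float]:
    """EM for the zero-inflated Poisson."""
    n = x.size
    n0 = int((x == 0).sum())
    total = float(x.sum())
    pi0 = 0.5 * n0 / n
    lam = max(total / max(n - n0 * 0.5, 1.0), _RATE_FLOOR)
    ll_old = -np.inf
    for _ in range(max_iter):
        # responsibility of the inflation mass for the zeros
        denom = pi0 + (1.0 - pi0) * np.exp(-lam)
        t = pi0 / denom if denom > 0 else 1.0
        pi0 = n0 * t / n
        lam = max(total / max(n - n0 * t, 1e-12), _RATE_FLOOR)
        ll = zip_loglik(x, pi0, lam)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-10):
            break
        ll_old = ll
    # never report a worse likelihood than the nested plain Poisson
    _, ll_p = fit_poisson(x)
    ll = zip_loglik(x, pi0, lam)
    if ll < ll_p:
        pi0, lam = 0.0, max(float(np.mean(x)), _RATE_FLOOR)
        ll = ll_p
    return ModelParams(pi0=pi0, lambda_=lam), float(ll)


def zinb_loglik(x: np.ndarray, pi0: float, size: float, prob: float) -> float:
    zero = x == 0
    n0 = int(zero.sum())
    ll = 0.0
    lp1 = np.log1p(-min(pi0, 1 - 1e-16))
    if n0:
        ll += n0 * logsumexp(
            [np.log(max(pi0, 1e-300)), lp1 + stats.nbinom.logpmf(0, size, prob)]
        )
    nz = x[~zero]
    if nz.size:
        ll += lp1 * nz.size + float(stats.nbinom.logpmf(nz, size, prob).sum())
    return float(ll)


def fit_zinb(x: np.ndarray) -> tuple[ModelParams, float, bool]:
    """Numeric MLE for the zero-inflated NB over (logit pi0, log size, log mean)."""
    n0frac = float((x == 0).mean())
    m_all = max(x.mean(), _RATE_FLOOR)
    n0 = int((x == 0).sum())
    nzvals, nzcounts = np.unique(x[x > 0], return_counts=True)
    n_nz = int(nzcounts.sum())

    def negll(theta):
        pi0 = 1.0 / (1.0 + np.exp(-theta[0]))
        size = np.exp(theta[1])
        mean = np.exp(theta[2])
        prob = size / (size + mean)
        lp1 = np.log1p(-min(pi0, 1 - 1e-16))
        ll = 0.0
        if n0:
            ll += n0 * logsumexp(
                [np.log(max(pi0, 1e-300)), lp1 + stats.nbinom.logpmf(0, size, prob)]
            )
        if n_nz:
            ll += lp1 * n_nz + float(nzcounts @ stats.nbinom.logpmf(nzvals, size, prob))
        return -ll

    starts = []
    for pi_init in (max(n0frac * 0.5, 0.02), max(n0frac * 0.9, 0.02)):
        m_init = m_all / max(1.0 - pi_init, 0.1)
        starts.append([np.log(pi_init / (1 - pi_init)), np.log(2.0), np.log(m_init)])
    best = None
    for s in starts:
        res = optimize.minimize(
            negll, s, method="Nelder-Mead",
            options={"maxiter": 800, "xatol": 1e-7, "fatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    pi0 = 1.0 / (1.0 + np.exp(-best.x[0]))
    size = float(np.exp(best.x[1]))
    mean = float(np.exp(best.x[2]))
    prob = size / (size + mean)
    params = ModelParams(pi0=float(pi0), nb_size=size, nb_prob=float(prob))
    return params, float(-best.fun), bool(best.success)
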