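"""EM for Gaussian mixtures with optional left-censoring at a cut point.

The same routine backs MG (no censoring), LTG (one component, censored),
LTMG (censored mixture) and the non-zero part of ZIMG.  Observations at or
below ``zcut`` enter the likelihood through the component CDF at ``zcut``
(left-censored), not as exact values.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, logsumexp

from ..errors import UnsupportedDataError
from ._base import SIGMA_FLOOR

_LOG_2PI = np.log(2.0 * np.pi)


def norm_logpdf(x, mu, sigma):
    z = (x - mu) / sigma
    return -0.5 * (_LOG_2PI + z * z) - np.log(sigma)


def norm_logcdf(x, mu, sigma):
    return log_ndtr((x - mu) / sigma)


def _kmeans_init(obs: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k-means initialisation (5 restarts, best inertia kept)."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=5, random_state=abs(int(seed)) % (2**31))
    labels = km.fit_predict(obs.reshape(-1, 1))
    mus = np.empty(k)
    sigmas = np.empty(k)
    weights = np.empty(k)
    for j in range(k):
        members = obs[labels == j]
        if members.size == 0:
            members = obs
        mus[j] = members.mean()
        sigmas[j] = max(members.std(), SIGMA_FLOOR, obs.std() / (4 * k) if obs.std() > 0 else SIGMA_FLOOR)
        weights[j] = max(members.size, 1) / obs.size
    weights /= weights.sum()
    order = np.argsort(mus)
    return weights[order], mus[order], sigmas[order]


def censored_mixture_loglik(x, weights, mus, sigmas, zcut=None):
    """Observed-data log-likelihood; values <= zcut are censored at zcut."""
    x = np.asarray(x, dtype=float)
    lw = np.log(np.maximum(weights, 1e-300))
    if zcut is None:
        comp = lw[None, :] + norm_logpdf(x[:, None], mus[None, :], sigmas[None, :])
        return float(logsumexp(comp, axis=1).sum())
    cens = x <= zcut
    obs = x[~cens]
    ll = 0.0
    if obs.size:
        comp = lw[None, :] + norm_logpdf(obs[:, None], mus[None, :], sigmas[None, :])
        ll += logsumexp(comp, axis=1).sum()
    ncens = int(cens.sum())
    if ncens:
        ll += ncens * logsumexp(lw + norm_logcdf(zcut, mus, sigmas))
    return float(ll)


def _em(obs, ncens, zcut, weights, mus, sigmas, max_iter, tol):
    """Run EM from the given starting point.  Returns (w, mu, sig, ll, converged)."""
    n = obs.size + ncens
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        lw = np.log(np.maximum(weights, 1e-300))
        # E-step
        if obs.size:
            logp = lw[None, :] + norm_logpdf(obs[:, None], mus[None, :], sigmas[None, :])
            norm = logsumexp(logp, axis=1)
            resp = np.exp(logp - norm[:, None])
            ll = norm.sum()
        else:
            resp = np.zeros((0, len(weights)))
            ll = 0.0
        if ncens:
            logc = lw + norm_logcdf(zcut, mus, sigmas)
            cnorm = logsumexp(logc)
            cresp = np.exp(logc - cnorm)
            ll += ncens * cnorm
            # conditional moments of X | X <= zcut under each component
            a = (zcut - mus) / sigmas
            log_haz = norm_logpdf(zcut, mus, sigmas) + np.log(sigmas) - log_ndtr(a)
            haz = np.exp(np.minimum(log_haz, 50.0))  # phi(a)/Phi(a), ~|a| for a << 0
            cmean = mus - sigmas * haz
            cvar = sigmas**2 * np.maximum(1.0 - a * haz - haz**2, 1e-12)
        else:
            cresp = np.zeros(len(weights))
            cmean = np.zeros(len(weights))
            cvar = np.zeros(len(weights))
        # M-step
        nk = resp.sum(axis=0) + ncens * cresp
        nk = np.maximum(nk, 1e-12)
        s1 = resp.T @ obs + ncens * cresp * cmean
        s2 = resp.T @ (obs * obs) + ncens * cresp * (cvar + cmean**2)
        weights = nk / n
        weights /= weights.sum()
        mus = s1 / nk
        sigmas = np.sqrt(np.maximum(s2 / nk - mus**2, SIGMA_FLOOR**2))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-10):
            converged = True
            break
        ll_old = ll
    order = np.argsort(mus)
    weights, mus, sigmas = weights[order], mus[order], sigmas[order]
    ll = censored_mixture_loglik(
        np.concatenate([obs, np.full(ncens, zcut if zcut is not None else 0.0)]),
        weights, mus, sigmas, zcut,
    )
    return weights, mus, sigmas, ll, converged


def fit_censored_mixture(
    x,
    n_components: int,
    zcut: float | None = None,
    seed: int = 0,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
):
    """Fit a K-component Gaussian mixture, censoring values <= zcut.

    Starts EM from a k-means initialisation and, when ``init`` is supplied
    (e.g. a split of the best (K-1)-component solution), also from that
    start; the higher-likelihood solution wins.  Components are returned
    sorted by ascending mean.
    """
    x = np.asarray(x, dtype=float)
    if zcut is None:
        obs, ncens = x, 0
    else:
        obs, ncens = x[x > zcut], int((x <= zcut).sum())
    if obs.size == 0:
        if n_components > 1:
            raise UnsupportedDataError("all observations censored; only K=1 possible")
        mu0 = zcut if zcut is not None else 0.0
        w, m, s, conv = np.array([1.0]), np.array([mu0 - 1.0]), np.array([1.0]), True
        ll = censored_mixture_loglik(x, w, m, s, zcut)
        return w, m, s, ll, conv
    if n_components > np.unique(obs).size:
        raise UnsupportedDataError(
            f"cannot fit {n_components} components to "
            f"{np.unique(obs).size} distinct observed values"
        )
    starts = []
    if n_components == 1:
        mu0 = obs.mean()
        sd0 = max(obs.std(), SIGMA_FLOOR)
        starts.append((np.array([1.0]), np.array([mu0]), np.array([sd0])))
    else:
        starts.append(_kmeans_init(obs, n_components, seed))
    if init is not None:
        starts.append(tuple(np.asarray(a, dtype=float).copy() for a in init))
    best = None
    for w0, m0, s0 in starts:
        out = _em(obs, ncens, zcut, w0.copy(), m0.copy(), s0.copy(), max_iter, tol)
        if best is None or out[3] > best[3]:
            best = out
    return best


def split_widest(weights, mus, sigmas):
    """Seed a (K+1)-start by splitting the widest component of a K-solution."""
    j = int(np.argmax(sigmas * weights))
    w = np.concatenate([np.delete(weights, j), [weights[j] / 2, weights[j] / 2]])
    m = np.concatenate([np.delete(mus, j), [mus[j] - sigmas[j] / 2, mus[j] + sigmas[j] / 2]])
    s = np.concatenate([np.delete(sigmas, j), [sigmas[j], sigmas[j]]])
    order = np.argsort(m)
    return w[order] / w.sum(), m[order], s[order]


def select_n_components(
    x,
    max_components: int,
    zcut: float | None = None,
    seed: int = 0,
    n_total: int | None = None,
):
    """Choose K in 1..max_components by BIC; returns the winning fit tuple.

    ``n_total`` overrides the sample size used in the BIC penalty (ZIMG fits
    the mixture on non-zero values only but is penalised on the full vector).
    """
    x = np.asarray(x, dtype=float)
    n = n_total if n_total is not None else x.size
    if zcut is None:
        distinct = np.unique(x).size
    else:
        distinct = np.unique(x[x > zcut]).size
    kmax = max(1, min(max_components, distinct))
    best = None
    prev = None
    prev_ll = -np.inf
    for k in range(1, kmax + 1):
        w, m, s, ll, conv = fit_censored_mixture(x, k, zcut=zcut, seed=seed)
        if prev is not None and ll < prev_ll - 1e-9 * abs(prev_ll):
            # k-means start fell short of the nested (k-1)-solution; retry
            # from a split of it, which can only improve the likelihood
            w2, m2, s2, ll2, conv2 = fit_censored_mixture(
                x, k, zcut=zcut, seed=seed, init=split_widest(*prev)
            )
            if ll2 > ll:
                w, m, s, ll, conv = w2, m2, s2, ll2, conv2
        bic = -2.0 * ll + (3 * k - 1) * np.log(max(n, 2))
        if best is None or bic < best[0]:
            best = (bic, w, m, s, ll, conv)
        elif k > 1:
            break  # BIC worsened; larger K will not recover
        prev = (w, m, s)
        prev_ll = ll
    _, w, m, s, ll, conv = best
    return w, m, s, ll, conv
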