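"""Fitters for the continuous unimodal models: G, ZIG, LTG."""

from __future__ import annotations

import numpy as np

from ._base import SIGMA_FLOOR, ModelParams
from ._mixture import censored_mixture_loglik, fit_censored_mixture, norm_logpdf


def fit_gaussian(x: np.ndarray) -> tuple[ModelParams, float]:
    mu = float(np.mean(x))
    sigma = max(float(np.std(x)), SIGMA_FLOOR)
    ll = float(norm_logpdf(x, mu, sigma).sum())
    return ModelParams(mu=mu, sigma=sigma), ll


def fit_zig(x: np.ndarray) -> tuple[ModelParams, float]:
    """Zero-inflated Gaussian: closed-form MLE.

    Exact zeros carry the inflation mass (the continuous part hits 0 with
    probability zero), so pi0 is the zero fraction and the Gaussian is fit
    on the non-zero values.
    """
    zero = x == 0
    pi0 = float(zero.mean())
    nz = x[~zero]
    if nz.size == 0:
        params = ModelParams(pi0=pi0, mu=0.0, sigma=SIGMA_FLOOR)
        return params, float(nz.size and 0.0) + x.size * np.log(max(pi0, 1e-300))
    mu = float(nz.mean())
    sigma = max(float(nz.std()), SIGMA_FLOOR)
    ll = 0.0
    if zero.any():
        ll += zero.sum() * np.log(max(pi0, 1e-300))
    ll += nz.size * np.log1p(-min(pi0, 1 - 1e-16)) + float(norm_logpdf(nz, mu, sigma).sum())
    return ModelParams(pi0=pi0, mu=mu, sigma=sigma), float(ll)


def fit_ltg(x: np.ndarray, zcut: float, seed: int = 0) -> tuple[ModelParams, float, bool]:
    """Left-censored Gaussian MLE (values <= zcut censored at zcut)."""
    w, m, s, ll, conv = fit_censored_mixture(x, 1, zcut=zcut, seed=seed)
    return ModelParams(mu=float(m[0]), sigma=float(s[0]), zcut=float(zcut)), float(ll), conv


def zig_loglik(x: np.ndarray, pi0: float, mu: float, sigma: float) -> float:
    zero = x == 0
    ll = 0.0
    if zero.any():
        ll += zero.sum() * np.log(max(pi0, 1e-300))
    nz = x[~zero]
    if nz.size:
        ll += nz.size * np.log1p(-min(pi0, 1 - 1e-16))
        ll += float(norm_logpdf(nz, mu, sigma).sum())
    return float(ll)
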