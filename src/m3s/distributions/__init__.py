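"""Densities, CDFs, samplers and fitters for the 11 candidate models."""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtr

from ..errors import InvalidParameterError, UnsupportedDataError
from ._base import (
    COMPLEXITY_RANK,
    CONTINUOUS_MODELS,
    COUNT_MODELS,
    LEFT_TRUNCATED_MODELS,
    MIXTURE_MODELS,
    SIGMA_FLOOR,
    ZERO_INFLATED_MODELS,
    ModelFit,
    ModelName,
    ModelParams,
)
from ._betapoisson import QUADRATURE_ORDER, bp_cdf, bp_loglik, fit_bp, sample_bp
from ._counts import fit_nb, fit_poisson, fit_zinb, fit_zip, zinb_loglik, zip_loglik
from ._gaussian import fit_gaussian, fit_ltg, fit_zig, zig_loglik
from ._mixture import (
    censored_mixture_loglik,
    fit_censored_mixture,
    norm_logpdf,
    select_n_components,
)

__all__ = [
    "ModelName", "ModelParams", "ModelFit",
    "COMPLEXITY_RANK", "COUNT_MODELS", "CONTINUOUS_MODELS", "MIXTURE_MODELS",
    "ZERO_INFLATED_MODELS", "LEFT_TRUNCATED_MODELS",
    "fit_model", "model_cdf", "model_cdf_pair", "model_sample",
    "model_loglik", "peak_count", "default_zcut",
]


def default_zcut(x: np.ndarray) -> float:
    """Default left-censoring point for a profile.

    The minimum observed value; when the profile contains exact zeros and
    positive values (e.g. after log(CPM+1)), the smallest positive value is
    used so the zeros fall into the censored mass.
    """
    x = np.asarray(x, dtype=float)
    m = float(x.min())
    if m == 0.0 and np.any(x > 0):
        return float(x[x > 0].min())
    return m


def _check_counts(x: np.ndarray, model: ModelName) -> None:
    if np.any(x < 0):
        raise UnsupportedDataError(f"{model.value} requires nonnegative values")
    if np.any(x != np.round(x)):
        raise UnsupportedDataError(f"{model.value} requires integer counts")


def fit_model(
    x,
    model: ModelName,
    max_components: int = 5,
    zcut: float | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit one candidate model to an expression vector by (penalised) MLE.

    Closed-form MLE where available (P, G, ZIG), profile/numeric MLE for
    NB/ZINB/BP, EM for ZIP and the Gaussian mixtures; for MG/ZIMG/LTMG the
    number of components is chosen by BIC over 1..max_components.  For
    LTG/LTMG values <= zcut are treated as left-censored at zcut
    (``zcut=None`` selects the default cut, see :func:`default_zcut`).
    Deterministic given ``seed``.
    """
    model = ModelName(model)
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise UnsupportedDataError("need at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise UnsupportedDataError("non-finite values in input")
    if np.unique(x).size == 1 and model not in (ModelName.P, ModelName.G):
        raise UnsupportedDataError(
            f"constant vector supported only by P or G, not {model.value}"
        )
    converged = True
    n_components = 1
    if model in COUNT_MODELS:
        _check_counts(x, model)
    if model is ModelName.P:
        params, ll = fit_poisson(x)
    elif model is ModelName.NB:
        params, ll = fit_nb(x)
    elif model is ModelName.ZIP:
        params, ll = fit_zip(x)
    elif model is ModelName.ZINB:
        params, ll, converged = fit_zinb(x)
    elif model is ModelName.BP:
        params, ll, converged = fit_bp(x)
    elif model is ModelName.G:
        params, ll = fit_gaussian(x)
    elif model is ModelName.ZIG:
        params, ll = fit_zig(x)
    elif model is ModelName.LTG:
        zc = default_zcut(x) if zcut is None else float(zcut)
        params, ll, converged = fit_ltg(x, zc, seed=seed)
    elif model is ModelName.MG:
        w, m, s, ll, converged = select_n_components(x, max_components, seed=seed)
        params = ModelParams(weights=w, mus=m, sigmas=s)
        n_components = len(w)
    elif model is ModelName.ZIMG:
        zero = x == 0
        pi0 = float(zero.mean())
        nz = x[~zero]
        if nz.size == 0:
            params = ModelParams(
                pi0=1.0, weights=[1.0], mus=[0.0], sigmas=[SIGMA_FLOOR]
            )
            ll = 0.0
        else:
            w, m, s, llmix, converged = select_n_components(
                nz, max_components, seed=seed, n_total=x.size
            )
            params = ModelParams(pi0=pi0, weights=w, mus=m, sigmas=s)
            n_components = len(w)
            ll = llmix + nz.size * np.log1p(-min(pi0, 1 - 1e-16))
            if zero.any():
                ll += zero.sum() * np.log(max(pi0, 1e-300))
    elif model is ModelName.LTMG:
        zc = default_zcut(x) if zcut is None else float(zcut)
        w, m, s, ll, converged = select_n_components(
            x, max_components, zcut=zc, seed=seed
        )
        params = ModelParams(weights=w, mus=m, sigmas=s, zcut=zc)
        n_components = len(w)
    else:  # pragma: no cover
        raise InvalidParameterError(f"unknown model {model}")
    params.validate(model)
    return ModelFit(
        model=model, params=params, loglik=float(ll),
        n_components=n_components, converged=bool(converged),
    )


def _mix_cdf(params: ModelParams, q: np.ndarray) -> np.ndarray:
    z = (q[:, None] - params.mus[None, :]) / params.sigmas[None, :]
    return ndtr(z) @ params.weights


def model_cdf(model: ModelName, params: ModelParams, q) -> np.ndarray:
    """CDF of ``model`` at the points ``q``.

    Left-truncated models use censoring semantics: all mass at or below
    zcut sits as a point mass at zcut, so F(q)=0 below zcut and equals the
    untruncated Gaussian (mixture) CDF from zcut upwards.
    """
    model = ModelName(model)
    params.validate(model)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if model is ModelName.P:
        return stats.poisson.cdf(q, params.lambda_)
    if model is ModelName.NB:
        return stats.nbinom.cdf(q, params.nb_size, params.nb_prob)
    if model is ModelName.ZIP:
        return params.pi0 * (q >= 0) + (1 - params.pi0) * stats.poisson.cdf(q, params.lambda_)
    if model is ModelName.ZINB:
        return params.pi0 * (q >= 0) + (1 - params.pi0) * stats.nbinom.cdf(
            q, params.nb_size, params.nb_prob
        )
    if model is ModelName.BP:
        return bp_cdf(q, params.bp_alpha, params.bp_beta, params.bp_scale)
    if model is ModelName.G:
        return ndtr((q - params.mu) / params.sigma)
    if model is ModelName.ZIG:
        return params.pi0 * (q >= 0) + (1 - params.pi0) * ndtr((q - params.mu) / params.sigma)
    if model is ModelName.LTG:
        base = ndtr((q - params.mu) / params.sigma)
        return np.where(q < params.zcut, 0.0, base)
    if model is ModelName.MG:
        return _mix_cdf(params, q)
    if model is ModelName.ZIMG:
        return params.pi0 * (q >= 0) + (1 - params.pi0) * _mix_cdf(params, q)
    if model is ModelName.LTMG:
        return np.where(q < params.zcut, 0.0, _mix_cdf(params, q))
    raise InvalidParameterError(f"unknown model {model}")  # pragma: no cover


def model_cdf_pair(model: ModelName, params: ModelParams, q) -> tuple[np.ndarray, np.ndarray]:
    """(F(q), F(q-)) — the CDF and its left limit, for KS on models with atoms."""
    model = ModelName(model)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    hi = model_cdf(model, params, q)
    if model in (ModelName.P, ModelName.NB, ModelName.BP):
        lo = model_cdf(model, params, q - 0.5)
    elif model in (ModelName.ZIP, ModelName.ZINB):
        base = (
            stats.poisson.cdf(q - 0.5, params.lambda_)
            if model is ModelName.ZIP
            else stats.nbinom.cdf(q - 0.5, params.nb_size, params.nb_prob)
        )
        lo = params.pi0 * (q > 0) + (1 - params.pi0) * base
    elif model in (ModelName.ZIG, ModelName.ZIMG):
        cont = (
            ndtr((q - params.mu) / params.sigma)
            if model is ModelName.ZIG
            else _mix_cdf(params, q)
        )
        lo = params.pi0 * (q > 0) + (1 - params.pi0) * cont
    elif model in LEFT_TRUNCATED_MODELS:
        base = (
            ndtr((q - params.mu) / params.sigma)
            if model is ModelName.LTG
            else _mix_cdf(params, q)
        )
        lo = np.where(q <= params.zcut, 0.0, base)
    else:
        lo = hi
    return hi, lo


def model_sample(
    model: ModelName,
    params: ModelParams,
    n: int,
    seed: int,
    lt_mode: str = "censor",
) -> np.ndarray:
    """Draw n i.i.d. samples; reproducible given seed.

    ``lt_mode`` controls LTG/LTMG generation: ``"censor"`` clamps draws
    below zcut to zcut (the fitting semantics); ``"truncate"`` rejects them.
    """
    model = ModelName(model)
    params.validate(model)
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if model is ModelName.P:
        return rng.poisson(params.lambda_, n).astype(float)
    if model is ModelName.NB:
        lam = rng.gamma(params.nb_size, (1 - params.nb_prob) / params.nb_prob, n)
        return rng.poisson(lam).astype(float)
    if model is ModelName.ZIP:
        out = rng.poisson(params.lambda_, n).astype(float)
        out[rng.random(n) < params.pi0] = 0.0
        return out
    if model is ModelName.ZINB:
        lam = rng.gamma(params.nb_size, (1 - params.nb_prob) / params.nb_prob, n)
        out = rng.poisson(lam).astype(float)
        out[rng.random(n) < params.pi0] = 0.0
        return out
    if model is ModelName.BP:
        return sample_bp(params.bp_alpha, params.bp_beta, params.bp_scale, n, rng)
    if model is ModelName.G:
        return rng.normal(params.mu, params.sigma, n)
    if model is ModelName.ZIG:
        out = rng.normal(params.mu, params.sigma, n)
        out[rng.random(n) < params.pi0] = 0.0
        return out
    if model in MIXTURE_MODELS:
        comp = rng.choice(len(params.weights), size=n, p=params.weights / params.weights.sum())
        out = rng.normal(params.mus[comp], params.sigmas[comp])
        if model is ModelName.ZIMG:
            out[rng.random(n) < params.pi0] = 0.0
        if model is ModelName.LTMG:
            out = _apply_lt(out, params.zcut, lt_mode, rng, params)
        return out
    if model is ModelName.LTG:
        out = rng.normal(params.mu, params.sigma, n)
        return _apply_lt(out, params.zcut, lt_mode, rng, params)
    raise InvalidParameterError(f"unknown model {model}")  # pragma: no cover


def _apply_lt(out, zcut, lt_mode, rng, params):
    if lt_mode == "censor":
        return np.maximum(out, zcut)
    if lt_mode != "truncate":
        raise InvalidParameterError(f"lt_mode must be censor or truncate, got {lt_mode!r}")
    # rejection below zcut
    for _ in range(1000):
        below = out < zcut
        if not below.any():
            return out
        k = int(below.sum())
        if params.mus is not None:
            comp = rng.choice(len(params.weights), size=k, p=params.weights / params.weights.sum())
            out[below] = rng.normal(params.mus[comp], params.sigmas[comp])
        else:
            out[below] = rng.normal(params.mu, params.sigma, k)
    raise InvalidParameterError("rejection sampling failed: zcut too far in the tail")


def model_loglik(model: ModelName, params: ModelParams, x) -> float:
    """Observed-data log-likelihood of ``x`` under ``model`` with ``params``."""
    model = ModelName(model)
    params.validate(model)
    x = np.asarray(x, dtype=float)
    if model is ModelName.P:
        return float(stats.poisson.logpmf(x, params.lambda_).sum())
    if model is ModelName.NB:
        return float(stats.nbinom.logpmf(x, params.nb_size, params.nb_prob).sum())
    if model is ModelName.ZIP:
        return zip_loglik(x, params.pi0, params.lambda_)
    if model is ModelName.ZINB:
        return zinb_loglik(x, params.pi0, params.nb_size, params.nb_prob)
    if model is ModelName.BP:
        return bp_loglik(x, params.bp_alpha, params.bp_beta, params.bp_scale)
    if model is ModelName.G:
        return float(norm_logpdf(x, params.mu, params.sigma).sum())
    if model is ModelName.ZIG:
        return zig_loglik(x, params.pi0, params.mu, params.sigma)
    if model is ModelName.LTG:
        return censored_mixture_loglik(
            x, np.array([1.0]), np.array([params.mu]), np.array([params.sigma]), params.zcut
        )
    if model is ModelName.MG:
        return censored_mixture_loglik(x, params.weights, params.mus, params.sigmas, None)
    if model is ModelName.ZIMG:
        zero = x == 0
        nz = x[~zero]
        ll = 0.0
        if zero.any():
            ll += zero.sum() * np.log(max(params.pi0, 1e-300))
        if nz.size:
            ll += nz.size * np.log1p(-min(params.pi0, 1 - 1e-16))
            ll += censored_mixture_loglik(nz, params.weights, params.mus, params.sigmas, None)
        return float(ll)
    if model is ModelName.LTMG:
        return censored_mixture_loglik(
            x, params.weights, params.mus, params.sigmas, params.zcut
        )
    raise InvalidParameterError(f"unknown model {model}")  # pragma: no cover


def peak_count(fit: ModelFit) -> int:
    """Number of (non-zero) peaks of a fitted model.

    Mixtures report their component count (the zero-inflation atom of ZIMG
    is not a peak, but every Gaussian component is); unimodal models report 1.
    """
    if not fit.converged:
        raise UnsupportedDataError("peak_count requires a converged fit")
    if fit.model in MIXTURE_MODELS:
        return int(fit.n_components)
    return 1
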