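"""Shared machinery for the parameter-recovery acceptance criterion.

For each model we define a fixed ground-truth parameter vector, a packing of
the free parameters into a flat vector, and compute asymptotic standard
errors from the numeric Hessian of the log-likelihood at the truth (observed
information).  A run passes when every component of the MLE lies within
3 SE of the truth.
"""

from __future__ import annotations

import numpy as np

from m3s.distributions import ModelName, ModelParams, model_loglik

TRUTHS: dict[ModelName, ModelParams] = {
    ModelName.P: ModelParams(lambda_=5.0),
    ModelName.NB: ModelParams(nb_size=3.0, nb_prob=3.0 / 13.0),  # mean 10
    ModelName.G: ModelParams(mu=2.0, sigma=1.5),
    ModelName.ZIP: ModelParams(pi0=0.3, lambda_=8.0),
    ModelName.ZINB: ModelParams(pi0=0.3, nb_size=3.0, nb_prob=3.0 / 13.0),
    ModelName.ZIG: ModelParams(pi0=0.3, mu=5.0, sigma=1.0),
    ModelName.LTG: ModelParams(mu=3.0, sigma=1.5, zcut=2.5),
    ModelName.BP: ModelParams(bp_alpha=0.5, bp_beta=0.5, bp_scale=50.0),
    ModelName.MG: ModelParams(weights=[0.4, 0.6], mus=[0.0, 6.0], sigmas=[1.0, 1.0]),
    ModelName.ZIMG: ModelParams(
        pi0=0.3, weights=[0.5, 0.5], mus=[3.0, 8.0], sigmas=[0.8, 0.8]
    ),
    ModelName.LTMG: ModelParams(
        weights=[0.5, 0.5], mus=[2.0, 7.0], sigmas=[0.8, 0.8], zcut=2.0
    ),
}


def pack(model: ModelName, p: ModelParams) -> np.ndarray:
    """Free parameters as a flat vector (weights: first K-1; NB: size, mean)."""
    if model is ModelName.P:
        return np.array([p.lambda_])
    if model is ModelName.NB:
        return np.array([p.nb_size, p.nb_size * (1 - p.nb_prob) / p.nb_prob])
    if model is ModelName.G:
        return np.array([p.mu, p.sigma])
    if model is ModelName.ZIP:
        return np.array([p.pi0, p.lambda_])
    if model is ModelName.ZINB:
        return np.array([p.pi0, p.nb_size, p.nb_size * (1 - p.nb_prob) / p.nb_prob])
    if model is ModelName.ZIG:
        return np.array([p.pi0, p.mu, p.sigma])
    if model is ModelName.LTG:
        return np.array([p.mu, p.sigma])
    if model is ModelName.BP:
        return np.array([p.bp_alpha, p.bp_beta, p.bp_scale])
    order = np.argsort(p.mus)
    w, mus, sig = p.weights[order], p.mus[order], p.sigmas[order]
    head = [p.pi0] if model is ModelName.ZIMG else []
    return np.array(head + list(w[:-1]) + list(mus) + list(sig))


def unpack(model: ModelName, theta: np.ndarray, template: ModelParams) -> ModelParams:
    """Inverse of :func:`pack`; ``template`` supplies K and zcut."""
    t = list(map(float, theta))
    if model is ModelName.P:
        return ModelParams(lambda_=t[0])
    if model is ModelName.NB:
        size, mean = t
        return ModelParams(nb_size=size, nb_prob=size / (size + mean))
    if model is ModelName.G:
        return ModelParams(mu=t[0], sigma=t[1])
    if model is ModelName.ZIP:
        return ModelParams(pi0=t[0], lambda_=t[1])
    if model is ModelName.ZINB:
        pi0, size, mean = t
        return ModelParams(pi0=pi0, nb_size=size, nb_prob=size / (size + mean))
    if model is ModelName.ZIG:
        return ModelParams(pi0=t[0], mu=t[1], sigma=t[2])
    if model is ModelName.LTG:
        return ModelParams(mu=t[0], sigma=t[1], zcut=template.zcut)
    if model is ModelName.BP:
        return ModelParams(bp_alpha=t[0], bp_beta=t[1], bp_scale=t[2])
    k = len(template.weights)
    if model is ModelName.ZIMG:
        pi0, t = t[0], t[1:]
    w = np.array(t[: k - 1] + [1.0 - sum(t[: k - 1])])
    mus = np.array(t[k - 1: 2 * k - 1])
    sig = np.array(t[2 * k - 1: 3 * k - 1])
    kw = dict(weights=w, mus=mus, sigmas=sig)
    if model is ModelName.ZIMG:
        kw["pi0"] = pi0
    if model is ModelName.LTMG:
        kw["zcut"] = template.zcut
    return ModelParams(**kw)


def _hessian(f, x0: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    n = x0.size
    h = np.maximum(np.abs(x0), 0.05) * rel
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def asymptotic_se(model: ModelName, x: np.ndarray, truth: ModelParams) -> np.ndarray:
    """SEs from the observed information at the true parameters."""
    theta0 = pack(model, truth)

    def ll(theta):
        return model_loglik(model, unpack(model, theta, truth), x)

    H = _hessian(ll, theta0)
    cov = np.linalg.pinv(-H)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)
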