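"""Synthetic data generators for benchmarking the model selector.

Three generators are provided: homogeneous per-distribution feature panels
(with parameters drawn from the auditable ranges in ``param_ranges.yaml``),
outlier injection into a panel, and platform-shaped matrices mimicking
saturated read counts, UMI counts with cell-varying dropout, and
near-zero-free FISH counts.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import distributions as dist
from .distributions import ModelName, ModelParams
from .errors import InvalidParameterError
from .io import ExpressionMatrix

__all__ = [
    "BenchmarkSpec", "DEFAULT_PARAM_RANGES", "draw_params",
    "simulate_panel", "inject_outliers", "simulate_platform",
]


def _load_default_ranges() -> dict:
    text = (
        importlib.resources.files("m3s").joinpath("param_ranges.yaml").read_text()
    )
    return yaml.safe_load(text)


DEFAULT_PARAM_RANGES: dict = _load_default_ranges()


@dataclass
class BenchmarkSpec:
    """Configuration of a simulation panel."""

    n_features_per_model: int = 100
    n_samples: int = 500
    models: list[ModelName] = field(default_factory=lambda: list(ModelName))
    outlier_fraction: float = 0.0
    param_ranges: dict = field(default_factory=lambda: DEFAULT_PARAM_RANGES)
    seed: int = 0

    def __post_init__(self) -> None:
        self.models = [ModelName(m) for m in self.models]
        if self.n_samples < 50:
            raise InvalidParameterError("n_samples must be >= 50")
        if not 0 <= self.outlier_fraction < 0.5:
            raise InvalidParameterError("outlier_fraction must be in [0, 0.5)")
        if self.n_features_per_model < 1:
            raise InvalidParameterError("n_features_per_model must be >= 1")


def _u(rng: np.random.Generator, lohi) -> float:
    lo, hi = float(lohi[0]), float(lohi[1])
    return float(rng.uniform(lo, hi))


def _mixture_pieces(r: dict, rng: np.random.Generator):
    klo, khi = r["n_components"]
    k = int(rng.integers(int(klo), int(khi) + 1))
    mu1 = _u(rng, r["mu1"])
    mus = [mu1]
    for _ in range(k - 1):
        mus.append(mus[-1] + _u(rng, r["gap"]))
    sigmas = [_u(rng, r["sigma"]) for _ in range(k)]
    floor = float(r.get("weight_floor", 0.0))
    w = rng.dirichlet(np.ones(k)) + floor
    w /= w.sum()
    return np.array(w), np.array(mus), np.array(sigmas), k


def draw_params(
    model: ModelName, rng: np.random.Generator, ranges: dict | None = None
) -> ModelParams:
    """Draw one parameter set for ``model`` uniformly from its ranges."""
    model = ModelName(model)
    ranges = DEFAULT_PARAM_RANGES if ranges is None else ranges
    if model.value not in ranges:
        raise InvalidParameterError(f"no parameter ranges for {model.value}")
    r = ranges[model.value]
    if model is ModelName.P:
        return ModelParams(lambda_=_u(rng, r["lambda"]))
    if model is ModelName.NB:
        size = _u(rng, r["size"])
        mean = _u(rng, r["mean"])
        return ModelParams(nb_size=size, nb_prob=size / (size + mean))
    if model is ModelName.G:
        return ModelParams(mu=_u(rng, r["mu"]), sigma=_u(rng, r["sigma"]))
    if model is ModelName.ZIP:
        return ModelParams(pi0=_u(rng, r["pi0"]), lambda_=_u(rng, r["lambda"]))
    if model is ModelName.ZINB:
        size = _u(rng, r["size"])
        mean = _u(rng, r["mean"])
        return ModelParams(
            pi0=_u(rng, r["pi0"]), nb_size=size, nb_prob=size / (size + mean)
        )
    if model is ModelName.ZIG:
        return ModelParams(
            pi0=_u(rng, r["pi0"]), mu=_u(rng, r["mu"]), sigma=_u(rng, r["sigma"])
        )
    if model is ModelName.LTG:
        mu = _u(rng, r["mu"])
        sigma = _u(rng, r["sigma"])
        zcut = mu + _u(rng, r["zcut_offset"]) * sigma
        return ModelParams(mu=mu, sigma=sigma, zcut=zcut)
    if model is ModelName.BP:
        return ModelParams(
            bp_alpha=_u(rng, r["alpha"]),
            bp_beta=_u(rng, r["beta"]),
            bp_scale=_u(rng, r["scale"]),
        )
    if model is ModelName.MG:
        w, mus, sigmas, _ = _mixture_pieces(r, rng)
        return ModelParams(weights=w, mus=mus, sigmas=sigmas)
    if model is ModelName.ZIMG:
        w, mus, sigmas, _ = _mixture_pieces(r, rng)
        return ModelParams(pi0=_u(rng, r["pi0"]), weights=w, mus=mus, sigmas=sigmas)
    if model is ModelName.LTMG:
        w, mus, sigmas, _ = _mixture_pieces(r, rng)
        zcut = mus[0] + _u(rng, r["zcut_offset"]) * sigmas[0]
        return ModelParams(weights=w, mus=mus, sigmas=sigmas, zcut=zcut)
    raise InvalidParameterError(f"unknown model {model}")  # pragma: no cover


def simulate_panel(spec: BenchmarkSpec) -> tuple[ExpressionMatrix, list[ModelName]]:
    """Simulate ``n_features_per_model`` rows from each model in the spec.

    Returns the matrix and the per-row truth labels; reproducible given the
    spec's seed.  Left-truncated rows are generated with censoring-to-zcut
    (matching the fitting semantics).
    """
    rng = np.random.default_rng(spec.seed)
    rows, truth, gene_ids = [], [], []
    for model in spec.models:
        for i in range(spec.n_features_per_model):
            params = draw_params(model, rng, spec.param_ranges)
            row = dist.model_sample(
                model, params, spec.n_samples, seed=int(rng.integers(2**31))
            )
            rows.append(row)
            truth.append(model)
            gene_ids.append(f"{model.value}_{i}")
    values = np.vstack(rows)
    sample_ids = [f"s{j}" for j in range(spec.n_samples)]
    return ExpressionMatrix(values, gene_ids, sample_ids), truth


def inject_outliers(
    matrix: ExpressionMatrix,
    truth: list[ModelName],
    outlier_model: ModelName,
    fraction: float,
    seed: int,
    param_ranges: dict | None = None,
) -> tuple[ExpressionMatrix, list[ModelName], np.ndarray]:
    """Replace a random minority of rows with draws from ``outlier_model``."""
    outlier_model = ModelName(outlier_model)
    if not 0 <= fraction < 0.5:
        raise InvalidParameterError("outlier fraction must stay a minority (< 0.5)")
    n_out = math.ceil(fraction * matrix.n_genes)
    mask = np.zeros(matrix.n_genes, dtype=bool)
    if n_out == 0:
        return matrix, list(truth), mask
    rng = np.random.default_rng(seed)
    rows = rng.choice(matrix.n_genes, size=n_out, replace=False)
    values = matrix.values.copy()
    truth = list(truth)
    for r in rows:
        params = draw_params(outlier_model, rng, param_ranges)
        values[r] = dist.model_sample(
            outlier_model, params, matrix.n_samples, seed=int(rng.integers(2**31))
        )
        truth[r] = outlier_model
        mask[r] = True
    out = ExpressionMatrix(values, matrix.gene_ids, matrix.sample_ids)
    return out, truth, mask


#: Global detection floor used by the saturated-platform generator.
SATURATED_FLOOR = 1.0


def simulate_platform(
    kind: str, n_genes: int, n_cells: int, seed: int
) -> ExpressionMatrix:
    """Platform-shaped matrices: ``saturated``, ``umi`` or ``fish``.

    - saturated: log-scale mixtures censored at a common global floor
      (SMART-seq-like: every gene shares one detection limit).
    - umi: integer counts with a cell-specific dropout rate drawn from
      Beta(2, 6) (10x-like: unsaturated, resolution varies by cell).
    - fish: integer counts from well-separated positive mixtures with a
      negligible zero fraction (scFISH-like).
    """
    if n_genes < 1 or n_cells < 1:
        raise InvalidParameterError("n_genes and n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty((n_genes, n_cells))
    if kind == "saturated":
        for g in range(n_genes):
            k = int(rng.integers(2, 4))
            mus = SATURATED_FLOOR + 0.3 + np.cumsum(
                np.concatenate([[0.0], rng.uniform(2.0, 4.0, k - 1)])
            )
            sigmas = rng.uniform(0.5, 0.9, k)
            w = rng.dirichlet(np.ones(k)) + 0.3
            w /= w.sum()
            params = ModelParams(weights=w, mus=mus, sigmas=sigmas, zcut=SATURATED_FLOOR)
            values[g] = dist.model_sample(
                ModelName.LTMG, params, n_cells, seed=int(rng.integers(2**31))
            )
    elif kind == "umi":
        dropout = rng.beta(2.0, 6.0, n_cells)
        for g in range(n_genes):
            k = int(rng.integers(1, 4))
            mus = np.cumsum(np.concatenate([[rng.uniform(1.0, 2.0)], rng.uniform(1.0, 2.0, k - 1)]))
            sigmas = rng.uniform(0.3, 0.6, k)
            comp = rng.choice(k, size=n_cells, p=np.full(k, 1.0 / k))
            log_mean = rng.normal(mus[comp], sigmas[comp])
            counts = rng.poisson(np.exp(log_mean)).astype(float)
            counts[rng.random(n_cells) < dropout] = 0.0
            values[g] = counts
    elif kind == "fish":
        for g in range(n_genes):
            k = int(rng.integers(2, 4))
            mus = np.cumsum(np.concatenate([[rng.uniform(8.0, 15.0)], rng.uniform(10.0, 25.0, k - 1)]))
            sigmas = 0.15 * mus
            w = rng.dirichlet(np.ones(k)) + 0.3
            w /= w.sum()
            comp = rng.choice(k, size=n_cells, p=w)
            values[g] = np.maximum(np.round(rng.normal(mus[comp], sigmas[comp])), 0.0)
    else:
        raise InvalidParameterError(f"unknown platform kind {kind!r}")
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{j}" for j in range(n_cells)]
    return ExpressionMatrix(values, gene_ids, cell_ids)
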