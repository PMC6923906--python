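"""Model selection: KS goodness-of-fit, BH-FDR, and parsimony-ordered choice.

Every candidate model is fit per gene; a model is "adequate" for a gene when
the BH-adjusted p-value of its KS statistic (adjusted per model, across
genes) exceeds the FDR threshold, and the least complex adequate model wins.
Rank ties go to the larger KS p-value; the ZIMG/LTMG tie can additionally be
adjudicated by a Mann-Whitney comparison of fitted peak counts across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import distributions as dist
from .distributions import (
    COMPLEXITY_RANK,
    CONTINUOUS_MODELS,
    COUNT_MODELS,
    ModelFit,
    ModelName,
    ZERO_INFLATED_MODELS,
)
from .errors import InvalidParameterError, M3SError, NotConvergedError
from .io import ExpressionMatrix
from .normalize import (
    DataCharacteristics,
    apply_normalization,
    assess_characteristics,
    select_normalization,
)

__all__ = [
    "SelectionResult", "ks_gof", "fdr_adjust", "candidate_models",
    "select_best", "peak_parsimony_test", "m3s",
]

_CANONICAL_ORDER = list(ModelName)


@dataclass
class SelectionResult:
    """Per-gene outcome: chosen model, the full fit table, and peak count."""

    gene: str
    best_model: ModelName | None
    fits: dict[ModelName, ModelFit]
    n_peaks: int
    adequate: bool
    transform: str = "identity"


def ks_gof(
    x,
    fit: ModelFit,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic and p-value for a fitted model.

    The statistic is sup over the observed points of the distance between
    the empirical CDF and the model CDF, comparing both the right value and
    the left limit so point masses (zero inflation, censoring, discrete
    support) are handled correctly.  The p-value comes from the Kolmogorov
    law; with ``n_boot > 0`` a parametric bootstrap (refit per replicate)
    replaces it.
    """
    if not fit.converged:
        raise NotConvergedError(f"{fit.model.value} fit did not converge")
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    vals, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n
    ecdf_hi = cum
    ecdf_lo = np.concatenate([[0.0], cum[:-1]])
    f_hi, f_lo = dist.model_cdf_pair(fit.model, fit.params, vals)
    d = float(max(np.max(np.abs(ecdf_hi - f_hi)), np.max(np.abs(ecdf_lo - f_lo))))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for b in range(n_boot):
            xb = dist.model_sample(fit.model, fit.params, n, int(rng.integers(2**31)))
            try:
                fb = dist.fit_model(
                    xb, fit.model, max_components=max(fit.n_components, 1),
                    zcut=fit.params.zcut, seed=b,
                )
                db, _ = ks_gof(xb, fb)
            except M3SError:
                continue
            if db >= d:
                exceed += 1
        return d, (1.0 + exceed) / (n_boot + 1.0)
    p = float(stats.kstwo.sf(d, n))
    return d, float(np.clip(p, 0.0, 1.0))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def candidate_models(
    chars: DataCharacteristics, transform: str = "identity"
) -> list[ModelName]:
    """Candidate models admissible for data with the given characteristics.

    Count models apply only to nonnegative integer matrices (they are fit on
    the raw scale); continuous models always apply (fit after the transform).
    Zero-inflated variants are dropped when the matrix has no zeros at all.
    """
    models: list[ModelName] = list(CONTINUOUS_MODELS)
    if chars.discretized and chars.nonnegative and not chars.has_negative_infinite:
        models += list(COUNT_MODELS)
    if chars.zero_fraction == 0:
        models = [m for m in models if m not in ZERO_INFLATED_MODELS]
    return sorted(models, key=lambda m: (COMPLEXITY_RANK[m], _CANONICAL_ORDER.index(m)))


def select_best(
    fits: list[ModelFit] | dict[ModelName, ModelFit],
    fdr_threshold: float = 0.1,
    prefer: ModelName | None = None,
) -> tuple[ModelName | None, bool]:
    """Pick the most parsimonious adequate model.

    Among fits with ``ks_fdr > fdr_threshold`` the minimal complexity rank
    wins; rank ties break toward ``prefer`` (if set), then the larger KS
    p-value, then fewer peaks.  When nothing passes, the largest-p fit is
    returned as provisional with ``adequate=False``.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    if not fits:
        raise InvalidParameterError("empty fit table")
    passing = [f for f in fits if np.isfinite(f.ks_fdr) and f.ks_fdr > fdr_threshold]
    if not passing:
        provisional = max(fits, key=lambda f: f.ks_pvalue if np.isfinite(f.ks_pvalue) else -1.0)
        return provisional.model, False

    def key(f: ModelFit):
        return (
            COMPLEXITY_RANK[f.model],
            0 if (prefer is not None and f.model is prefer) else 1,
            -f.ks_pvalue,
            dist.peak_count(f) if f.converged else f.n_components,
        )

    best = min(passing, key=key)
    return best.model, True


def peak_parsimony_test(peak_counts_a, peak_counts_b) -> float:
    """One-sided Mann-Whitney p-value for "family a fits fewer peaks than b"."""
    a = np.asarray(peak_counts_a, dtype=float)
    b = np.asarray(peak_counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("peak count vectors must be nonempty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 0.5
    res = stats.mannwhitneyu(
        a, b, alternative="less", use_continuity=False, method="asymptotic"
    )
    return float(res.pvalue)


def _gene_zcut(vec: np.ndarray) -> float:
    return dist.default_zcut(vec)


def _fit_gene(
    raw_vec: np.ndarray,
    trans_vec: np.ndarray,
    models: list[ModelName],
    max_components: int,
    seed: int,
    gene_idx: int,
    bootstrap_ks: bool,
) -> dict[ModelName, ModelFit]:
    fits: dict[ModelName, ModelFit] = {}
    for m_idx, model in enumerate(models):
        vec = raw_vec if model in COUNT_MODELS else trans_vec
        if model in ZERO_INFLATED_MODELS and not np.any(vec == 0):
            continue  # pi0 unidentifiable without zeros
        if np.unique(vec).size == 1 and model not in (ModelName.P, ModelName.G):
            continue
        fit_seed = (seed * 1000003 + gene_idx * 131 + m_idx) % (2**31)
        try:
            fit = dist.fit_model(
                vec, model, max_components=max_components, seed=fit_seed
            )
        except M3SError:
            continue
        if fit.converged:
            n_boot = 200 if bootstrap_ks else 0
            fit.ks_stat, fit.ks_pvalue = ks_gof(vec, fit, n_boot=n_boot, seed=fit_seed)
        fits[model] = fit
    return fits


def m3s(
    matrix: ExpressionMatrix,
    fdr_threshold: float = 0.1,
    max_components: int = 5,
    seed: int = 0,
    normalization: str = "auto",
    bootstrap_ks: bool = False,
) -> list[SelectionResult]:
    """Select the most parsimonious adequate model for every gene.

    Pipeline: assess characteristics -> choose/apply normalization -> fit all
    candidate models per gene (count models on the raw scale, continuous
    models on the transformed scale) -> BH-FDR per model across genes ->
    parsimony selection, with the ZIMG/LTMG rank tie adjudicated by the
    across-gene Mann-Whitney peak-count test when enough genes qualify.
    Deterministic given ``seed``; results follow the input gene order.
    """
    if matrix.n_genes < 1 or matrix.values.size == 0:
        raise InvalidParameterError("matrix must contain at least one gene")
    if matrix.n_samples < 10:
        raise InvalidParameterError("need at least 10 samples")
    chars = assess_characteristics(matrix)
    choice = select_normalization(chars) if normalization == "auto" else normalization
    transformed = apply_normalization(matrix, choice)
    keep = np.array(
        [s not in transformed.zero_library_columns for s in matrix.sample_ids]
    )
    raw_v = matrix.values[:, keep]
    trans_v = transformed.values[:, keep]
    models = candidate_models(chars, transformed.transform_applied)

    all_fits: list[dict[ModelName, ModelFit]] = []
    for g_idx in range(matrix.n_genes):
        try:
            fits = _fit_gene(
                raw_v[g_idx], trans_v[g_idx], models, max_components,
                seed, g_idx, bootstrap_ks,
            )
        except M3SError as exc:
            raise type(exc)(f"gene {matrix.gene_ids[g_idx]}: {exc}") from exc
        all_fits.append(fits)

    # BH per model across genes
    for model in models:
        idx = [i for i, f in enumerate(all_fits) if model in f and np.isfinite(f[model].ks_pvalue)]
        if not idx:
            continue
        adj = fdr_adjust([all_fits[i][model].ks_pvalue for i in idx])
        for i, a in zip(idx, adj):
            all_fits[i][model].ks_fdr = float(a)

    prefer = _adjudicate_mixture_tie(all_fits, fdr_threshold)

    results: list[SelectionResult] = []
    for g_idx, fits in enumerate(all_fits):
        gene = matrix.gene_ids[g_idx]
        if not fits:
            results.append(SelectionResult(gene, None, {}, 0, False, choice))
            continue
        best, adequate = select_best(fits, fdr_threshold, prefer=prefer)
        n_peaks = dist.peak_count(fits[best]) if (best is not None and fits[best].converged) else 0
        results.append(
            SelectionResult(gene, best, fits, n_peaks, adequate, choice)
        )
    return results


def _adjudicate_mixture_tie(
    all_fits: list[dict[ModelName, ModelFit]],
    fdr_threshold: float,
    min_genes: int = 20,
    alpha: float = 0.05,
) -> ModelName | None:
    """Mann-Whitney adjudication of the ZIMG/LTMG complexity-rank tie.

    When both families pass the FDR rule on enough genes, the family fitting
    systematically fewer peaks is preferred for rank ties.
    """
    pair = (ModelName.ZIMG, ModelName.LTMG)
    both = [
        f for f in all_fits
        if all(
            m in f and np.isfinite(f[m].ks_fdr) and f[m].ks_fdr > fdr_threshold
            for m in pair
        )
    ]
    if len(both) < min_genes:
        return None
    pa = [dist.peak_count(f[pair[0]]) for f in both]
    pb = [dist.peak_count(f[pair[1]]) for f in both]
    if peak_parsimony_test(pa, pb) < alpha:
        return pair[0]
    if peak_parsimony_test(pb, pa) < alpha:
        return pair[1]
    return None
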