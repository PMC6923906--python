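"""Peak-membership differential expression test.

Samples are assigned to the peaks of each gene's selected model by maximum
posterior probability (zeros / censored values form a label-0 mass), and
each (gene, peak, class) triple is scored with an upper-tail hypergeometric
enrichment p-value, BH-adjusted across all triples tested in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import distributions as dist
from .distributions import (
    LEFT_TRUNCATED_MODELS,
    MIXTURE_MODELS,
    ModelFit,
    ModelName,
    ZERO_INFLATED_MODELS,
)
from .distributions._mixture import norm_logpdf
from .errors import InvalidParameterError, NotConvergedError
from .io import ExpressionMatrix
from .normalize import apply_normalization, assess_characteristics, select_normalization
from .select import SelectionResult, fdr_adjust

__all__ = ["PeakAssignment", "DETestResult", "assign_peaks", "hypergeom_enrichment", "m3s_test"]


@dataclass
class PeakAssignment:
    """Per-sample peak labels: 0 = zero/censored mass, 1..K = peaks by ascending mean."""

    gene: str
    labels: np.ndarray


@dataclass
class DETestResult:
    gene: str
    peak: int
    class_name: str
    overlap: int
    peak_size: int
    class_size: int
    population: int
    p_value: float
    fdr: float = float("nan")


def assign_peaks(x, fit: ModelFit, gene: str = "") -> PeakAssignment:
    """Assign each sample to a peak of the fitted model.

    Mixture components are ranked by ascending mean; each sample goes to the
    argmax-posterior component (posterior ties break toward the lower peak).
    Exact zeros under zero-inflated models and values at/below zcut under
    left-truncated models receive label 0.  Unimodal fits label everything 1.
    """
    if not fit.converged:
        raise NotConvergedError(f"{fit.model.value} fit did not converge")
    x = np.asarray(x, dtype=float)
    labels = np.ones(x.size, dtype=int)
    p = fit.params
    if fit.model in MIXTURE_MODELS:
        order = np.argsort(p.mus)
        w, mus, sigmas = p.weights[order], p.mus[order], p.sigmas[order]
        logp = np.log(np.maximum(w, 1e-300))[None, :] + norm_logpdf(
            x[:, None], mus[None, :], sigmas[None, :]
        )
        # argmax returns the first (lowest-mean) component on exact ties
        labels = np.argmax(logp, axis=1) + 1
    if fit.model in ZERO_INFLATED_MODELS:
        labels[x == 0] = 0
    if fit.model in LEFT_TRUNCATED_MODELS:
        labels[x <= p.zcut] = 0
    return PeakAssignment(gene=gene, labels=labels)


def hypergeom_enrichment(
    overlap: int, peak_size: int, class_size: int, population: int
) -> float:
    """Upper-tail hypergeometric probability P[X >= overlap].

    X counts the class members in a size-``peak_size`` draw without
    replacement from ``population`` samples of which ``class_size`` belong
    to the class.
    """
    if not (0 <= overlap <= min(peak_size, class_size)):
        raise InvalidParameterError(
            f"overlap {overlap} inconsistent with peak {peak_size} / class {class_size}"
        )
    if peak_size > population or class_size > population:
        raise InvalidParameterError("peak/class larger than population")
    if peak_size + class_size - overlap > population:
        raise InvalidParameterError("counts exceed population")
    return float(stats.hypergeom.sf(overlap - 1, population, class_size, peak_size))


def m3s_test(
    matrix: ExpressionMatrix,
    classes: dict[str, str] | list[str],
    selection: list[SelectionResult],
    fdr_threshold: float = 0.05,
    top_peak_only: bool = False,
) -> list[DETestResult]:
    """Hypergeometric enrichment of peak membership in sample classes.

    For every gene with at least one non-zero peak and every (peak, class)
    pair, tests whether the samples under the peak over-represent the class;
    BH-FDR is computed across all tested triples.  ``top_peak_only``
    restricts testing to each gene's highest-mean peak.
    """
    if isinstance(classes, dict):
        missing = [s for s in matrix.sample_ids if s not in classes]
        if missing:
            raise InvalidParameterError(f"samples without class label: {missing[:5]}")
        labels = np.array([classes[s] for s in matrix.sample_ids])
    else:
        labels = np.asarray(classes)
        if labels.size != matrix.n_samples:
            raise InvalidParameterError(
                f"{labels.size} class labels for {matrix.n_samples} samples"
            )
    if matrix.transform_applied is not None:
        transformed = matrix
    elif selection and getattr(selection[0], "transform", None):
        # re-apply the transform the fits were computed on
        transformed = apply_normalization(matrix, selection[0].transform)
    else:
        chars = assess_characteristics(matrix)
        transformed = apply_normalization(matrix, select_normalization(chars))
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    population = matrix.n_samples
    class_names = sorted(set(labels.tolist()))
    results: list[DETestResult] = []
    for sel in selection:
        if sel.best_model is None or sel.gene not in gene_index:
            continue
        fit = sel.fits.get(sel.best_model)
        if fit is None or not fit.converged:
            continue
        vec = transformed.values[gene_index[sel.gene]]
        assignment = assign_peaks(vec, fit, gene=sel.gene)
        peaks = sorted(set(assignment.labels.tolist()) - {0})
        if not peaks:
            continue
        if top_peak_only:
            peaks = [max(peaks)]
        for peak in peaks:
            in_peak = assignment.labels == peak
            peak_size = int(in_peak.sum())
            for cname in class_names:
                in_class = labels == cname
                class_size = int(in_class.sum())
                overlap = int((in_peak & in_class).sum())
                p = hypergeom_enrichment(overlap, peak_size, class_size, population)
                results.append(
                    DETestResult(
                        gene=sel.gene, peak=int(peak), class_name=str(cname),
                        overlap=overlap, peak_size=peak_size,
                        class_size=class_size, population=population, p_value=p,
                    )
                )
    if results:
        adj = fdr_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.fdr = float(a)
    return results
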