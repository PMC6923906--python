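"""End-to-end simulation benchmarks: identification accuracy and outlier recall.

Each generating distribution gets its own homogeneous panel (features of one
model, parameters drawn per feature), which is run through the full selector
with no extra normalization (the data are already on the model's scale); a
feature is scored correct when the selected model names the generator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .distributions import ModelName
from .select import m3s
from .simulate import BenchmarkSpec, inject_outliers, simulate_panel

__all__ = [
    "BenchmarkResult", "OutlierBenchmarkResult",
    "run_model_benchmark", "run_outlier_benchmark", "DEFAULT_OUTLIER_PAIRS",
]


@dataclass
class BenchmarkResult:
    per_model_accuracy: dict[str, float]
    overall_accuracy: float
    n_features_per_model: int
    n_samples: int
    selections: dict[str, list] = field(default_factory=dict, repr=False)


@dataclass
class OutlierBenchmarkResult:
    per_pair_recall: dict[tuple[str, str], float]
    mean_recall: float


def run_model_benchmark(
    n_features_per_model: int = 30,
    n_samples: int = 500,
    models: list[ModelName] | None = None,
    fdr_threshold: float = 0.1,
    max_components: int = 5,
    seed: int = 0,
) -> BenchmarkResult:
    """Per-distribution identification accuracy over homogeneous panels."""
    models = list(ModelName) if models is None else [ModelName(m) for m in models]
    per_model: dict[str, float] = {}
    selections: dict[str, list] = {}
    n_correct = 0
    n_total = 0
    for m_idx, model in enumerate(models):
        spec = BenchmarkSpec(
            n_features_per_model=n_features_per_model,
            n_samples=n_samples,
            models=[model],
            seed=seed * 7919 + m_idx,
        )
        matrix, truth = simulate_panel(spec)
        results = m3s(
            matrix, fdr_threshold=fdr_threshold, max_components=max_components,
            seed=seed, normalization="none",
        )
        correct = sum(
            1 for r, t in zip(results, truth) if r.best_model is t
        )
        per_model[model.value] = correct / len(results)
        selections[model.value] = results
        n_correct += correct
        n_total += len(results)
    return BenchmarkResult(
        per_model_accuracy=per_model,
        overall_accuracy=n_correct / n_total,
        n_features_per_model=n_features_per_model,
        n_samples=n_samples,
        selections=selections,
    )


#: (majority model, outlier model) pairs keeping one data type per panel.
DEFAULT_OUTLIER_PAIRS: list[tuple[ModelName, ModelName]] = [
    (ModelName.P, ModelName.ZIP),
    (ModelName.NB, ModelName.ZINB),
    (ModelName.ZIP, ModelName.P),
    (ModelName.G, ModelName.MG),
    (ModelName.MG, ModelName.ZIMG),
    (ModelName.LTG, ModelName.G),
]


def run_outlier_benchmark(
    pairs: list[tuple[ModelName, ModelName]] | None = None,
    n_majority: int = 95,
    n_outliers: int = 5,
    n_samples: int = 500,
    fdr_threshold: float = 0.1,
    max_components: int = 5,
    seed: int = 0,
) -> OutlierBenchmarkResult:
    """Recall of planted outlier features.

    A feature is called an outlier when its selected model differs from the
    panel's modal selected model; recall is the fraction of planted outliers
    so called, averaged over the (majority, outlier) pairs.
    """
    pairs = DEFAULT_OUTLIER_PAIRS if pairs is None else [
        (ModelName(a), ModelName(b)) for a, b in pairs
    ]
    per_pair: dict[tuple[str, str], float] = {}
    for p_idx, (majority, outlier) in enumerate(pairs):
        n_total = n_majority + n_outliers
        spec = BenchmarkSpec(
            n_features_per_model=n_total,
            n_samples=n_samples,
            models=[majority],
            seed=seed * 104729 + p_idx,
        )
        matrix, truth = simulate_panel(spec)
        matrix, truth, mask = inject_outliers(
            matrix, truth, outlier, n_outliers / n_total, seed=seed * 104729 + p_idx + 1,
        )
        results = m3s(
            matrix, fdr_threshold=fdr_threshold, max_components=max_components,
            seed=seed, normalization="none",
        )
        chosen = [r.best_model for r in results]
        modal = Counter(chosen).most_common(1)[0][0]
        called = np.array([c is not modal for c in chosen])
        recall = float(called[mask].mean())
        per_pair[(majority.value, outlier.value)] = recall
    return OutlierBenchmarkResult(
        per_pair_recall=per_pair,
        mean_recall=float(np.mean(list(per_pair.values()))),
    )
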