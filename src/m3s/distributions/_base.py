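"""Model names, parameter container, and fit record."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ..errors import InvalidParameterError

SIGMA_FLOOR = 1e-4


class ModelName(str, Enum):
    """The eleven candidate models, ordered by complexity rank."""

    P = "P"
    NB = "NB"
    G = "G"
    ZIP = "ZIP"
    ZINB = "ZINB"
    ZIG = "ZIG"
    LTG = "LTG"
    BP = "BP"
    MG = "MG"
    ZIMG = "ZIMG"
    LTMG = "LTMG"

    @property
    def complexity_rank(self) -> int:
        return COMPLEXITY_RANK[self]


# Parsimony ordering: P < {NB, G} < ZIP < {ZINB, ZIG, LTG} < BP < MG < {ZIMG, LTMG}
COMPLEXITY_RANK: dict[ModelName, int] = {
    ModelName.P: 0,
    ModelName.NB: 1,
    ModelName.G: 1,
    ModelName.ZIP: 2,
    ModelName.ZINB: 3,
    ModelName.ZIG: 3,
    ModelName.LTG: 3,
    ModelName.BP: 4,
    ModelName.MG: 5,
    ModelName.ZIMG: 6,
    ModelName.LTMG: 6,
}

COUNT_MODELS = frozenset(
    {ModelName.P, ModelName.NB, ModelName.ZIP, ModelName.ZINB, ModelName.BP}
)
CONTINUOUS_MODELS = frozenset(
    {ModelName.G, ModelName.ZIG, ModelName.LTG, ModelName.MG, ModelName.ZIMG, ModelName.LTMG}
)
MIXTURE_MODELS = frozenset({ModelName.MG, ModelName.ZIMG, ModelName.LTMG})
ZERO_INFLATED_MODELS = frozenset(
    {ModelName.ZIP, ModelName.ZINB, ModelName.ZIG, ModelName.ZIMG}
)
LEFT_TRUNCATED_MODELS = frozenset({ModelName.LTG, ModelName.LTMG})


@dataclass
class ModelParams:
    """Union of parameters across the candidate models.

    Only the fields relevant to a given model are populated:

    - ``lambda_``: Poisson rate (P, ZIP)
    - ``nb_size``, ``nb_prob``: negative binomial shape / success prob (NB, ZINB)
    - ``mu``, ``sigma``: Gaussian location / scale (G, ZIG, LTG)
    - ``pi0``: zero-inflation mass (ZIP, ZINB, ZIG, ZIMG)
    - ``weights``, ``mus``, ``sigmas``: mixture components (MG, ZIMG, LTMG)
    - ``zcut``: left-censoring point (LTG, LTMG)
    - ``bp_alpha``, ``bp_beta``, ``bp_scale``: Beta-Poisson parameters (BP)
    """

    lambda_: float | None = None
    nb_size: float | None = None
    nb_prob: float | None = None
    mu: float | None = None
    sigma: float | None = None
    pi0: float | None = None
    weights: np.ndarray | None = None
    mus: np.ndarray | None = None
    sigmas: np.ndarray | None = None
    zcut: float | None = None
    bp_alpha: float | None = None
    bp_beta: float | None = None
    bp_scale: float | None = None

    def __post_init__(self) -> None:
        for name in ("weights", "mus", "sigmas"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def validate(self, model: ModelName) -> None:
        """Raise :class:`InvalidParameterError` on any violated invariant."""
        def pos(name):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{model.value}: {name} must be > 0, got {v}")

        if model in (ModelName.P, ModelName.ZIP):
            pos("lambda_")
        if model in (ModelName.NB, ModelName.ZINB):
            pos("nb_size")
            if self.nb_prob is None or not 0 < self.nb_prob <= 1:
                raise InvalidParameterError(
                    f"{model.value}: nb_prob must be in (0, 1], got {self.nb_prob}"
                )
        if model in (ModelName.G, ModelName.ZIG, ModelName.LTG):
            if self.mu is None or not np.isfinite(self.mu):
                raise InvalidParameterError(f"{model.value}: mu must be finite")
            pos("sigma")
        if model in ZERO_INFLATED_MODELS:
            if self.pi0 is None or not 0 <= self.pi0 <= 1:
                raise InvalidParameterError(
                    f"{model.value}: pi0 must be in [0, 1], got {self.pi0}"
                )
        if model in MIXTURE_MODELS:
            if self.weights is None or self.mus is None or self.sigmas is None:
                raise InvalidParameterError(f"{model.value}: mixture params missing")
            k = len(self.weights)
            if k < 1 or len(self.mus) != k or len(self.sigmas) != k:
                raise InvalidParameterError(
                    f"{model.value}: inconsistent component counts"
                )
            if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-8:
                raise InvalidParameterError(
                    f"{model.value}: weights must be nonnegative and sum to 1"
                )
            if np.any(self.sigmas <= 0):
                raise InvalidParameterError(f"{model.value}: sigmas must be > 0")
        if model in LEFT_TRUNCATED_MODELS:
            if self.zcut is None or not np.isfinite(self.zcut):
                raise InvalidParameterError(f"{model.value}: zcut must be finite")
        if model is ModelName.BP:
            pos("bp_alpha")
            pos("bp_beta")
            pos("bp_scale")

    @property
    def n_components(self) -> int:
        return 1 if self.weights is None else len(self.weights)

    def as_dict(self, model: ModelName) -> dict[str, object]:
        """Flat dict of the fields relevant to ``model`` (for serialization)."""
        out: dict[str, object] = {}
        for f in (
            "lambda_", "nb_size", "nb_prob", "mu", "sigma", "pi0", "zcut",
            "bp_alpha", "bp_beta", "bp_scale",
        ):
            v = getattr(self, f)
            if v is not None:
                out[f] = float(v)
        for f in ("weights", "mus", "sigmas"):
            v = getattr(self, f)
            if v is not None:
                out[f] = [float(x) for x in v]
        return out


@dataclass
class ModelFit:
    """A fitted model for one expression vector.

    ``ks_stat``/``ks_pvalue`` are filled by the selection layer;
    ``ks_fdr`` after Benjamini-Hochberg adjustment across genes.
    """

    model: ModelName
    params: ModelParams
    loglik: float
    n_components: int = 1
    converged: bool = True
    ks_stat: float = float("nan")
    ks_pvalue: float = float("nan")
    ks_fdr: float = float("nan")

    def to_tsv_row(self) -> str:
        pd = self.params.as_dict(self.model)
        pstr = ";".join(
            f"{k}={','.join(f'{x:.6g}' for x in v) if isinstance(v, list) else f'{v:.6g}'}"
            for k, v in pd.items()
        )
        fields = [
            self.model.value,
            str(self.n_components),
            pstr,
            f"{self.loglik:.6g}",
            f"{self.ks_stat:.6g}",
            f"{self.ks_pvalue:.6g}",
        ]
        return "\t".join(fields)
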