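"""Data-characteristic screens and the five normalizations.

The pipeline first screens the matrix for four properties (nonnegativity,
zero proportion, discreteness, presence of -inf) and picks one of
log, log(x+1), CPM, log(CPM), log(CPM+1) or no transform accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, MatrixFormatError
from .io import ExpressionMatrix

__all__ = [
    "DataCharacteristics",
    "TRANSFORMS",
    "assess_characteristics",
    "select_normalization",
    "apply_normalization",
]

#: Recognised transform names.
TRANSFORMS = ("log", "log1p", "cpm", "log_cpm", "log_cpm1p", "identity")

#: Default threshold above which the zero proportion counts as "high".
ZERO_PROPORTION_THRESHOLD = 0.05


@dataclass(frozen=True)
class DataCharacteristics:
    """The four boolean screens plus the raw zero fraction."""

    nonnegative: bool
    high_zero_proportion: bool
    discretized: bool
    has_negative_infinite: bool
    zero_fraction: float


def assess_characteristics(
    matrix: ExpressionMatrix,
    zero_threshold: float = ZERO_PROPORTION_THRESHOLD,
) -> DataCharacteristics:
    """Evaluate the data-characteristic screens on a raw matrix.

    Entries must be finite or -inf (already-log data); NaN or +inf raise.
    The flags do not depend on row/column order.
    """
    v = matrix.values
    if v.size == 0:
        raise MatrixFormatError("empty matrix")
    if np.any(np.isnan(v)) or np.any(v == np.inf):
        raise MatrixFormatError("matrix contains NaN or +inf entries")
    finite = v[np.isfinite(v)]
    zero_fraction = float(np.mean(v == 0))
    return DataCharacteristics(
        nonnegative=bool(np.all(v >= 0)),
        high_zero_proportion=zero_fraction > zero_threshold,
        discretized=bool(np.all(finite == np.round(finite))),
        has_negative_infinite=bool(np.any(v == -np.inf)),
        zero_fraction=zero_fraction,
    )


def select_normalization(chars: DataCharacteristics) -> str:
    """Map data characteristics to a transform.

    Decision tree: data already on a signed/log scale (negatives or -inf)
    is left alone; integer counts get log(CPM+1) when zeros are present and
    log(CPM) otherwise; positive reals get log(x+1) with zeros, log without.
    """
    if chars.has_negative_infinite or not chars.nonnegative:
        return "identity"
    has_zeros = chars.zero_fraction > 0
    if chars.discretized:
        return "log_cpm1p" if has_zeros else "log_cpm"
    return "log1p" if has_zeros else "log"


def _cpm(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    colsums = values.sum(axis=0)
    zero_cols = colsums == 0
    safe = np.where(zero_cols, 1.0, colsums)
    return values * 1e6 / safe, zero_cols


def apply_normalization(matrix: ExpressionMatrix, choice: str) -> ExpressionMatrix:
    """Apply a transform; the result records the transform name.

    CPM scales each column to a library size of 1e6 (all-zero columns stay
    zero and are recorded in ``zero_library_columns``); logs are natural.
    """
    if choice not in TRANSFORMS and choice != "none":
        raise InvalidParameterError(f"unknown normalization {choice!r}")
    v = matrix.values
    zero_cols = np.zeros(matrix.n_samples, dtype=bool)
    if choice in ("identity", "none"):
        out = v.copy()
        choice = "identity"
    elif choice == "log":
        if np.any(v <= 0):
            raise InvalidParameterError("log requires strictly positive entries")
        out = np.log(v)
    elif choice == "log1p":
        if np.any(v < 0):
            raise InvalidParameterError("log1p requires nonnegative entries")
        out = np.log1p(v)
    else:
        cpm, zero_cols = _cpm(v)
        if choice == "cpm":
            out = cpm
        elif choice == "log_cpm":
            if np.any(cpm[:, ~zero_cols] <= 0):
                raise InvalidParameterError("log(CPM) requires strictly positive entries")
            out = np.where(zero_cols[None, :], 0.0, np.log(np.maximum(cpm, 1e-300)))
        else:  # log_cpm1p
            if np.any(v < 0):
                raise InvalidParameterError("log(CPM+1) requires nonnegative entries")
            out = np.log1p(cpm)
    result = matrix.with_values(out, transform=choice)
    result.zero_library_columns = [
        matrix.sample_ids[j] for j in np.nonzero(zero_cols)[0]
    ]
    return result
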