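"""Expression matrix container and readers/writers for the standard formats.

Genes are rows, samples are columns throughout the package.  Dense TSV/CSV
(first column = gene ids, header = sample ids) and CellRanger-style
MatrixMarket directories are supported; gzip is handled transparently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MatrixFormatError

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix", "read_classes"]


@dataclass
class ExpressionMatrix:
    """A gene x sample numeric matrix with row/column identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
    gene_ids : sequence of unique gene identifiers
    sample_ids : sequence of unique sample identifiers
    transform_applied : name of the normalization applied, or None for raw data
    zero_library_columns : sample ids whose column summed to zero under CPM
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    transform_applied: str | None = None
    zero_library_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("expression matrix must be 2-dimensional")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise MatrixFormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise MatrixFormatError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise MatrixFormatError(f"duplicate {kind} ids: {sorted(dupes)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def with_values(self, values: np.ndarray, transform: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, transform_applied=transform)


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


def read_matrix(path: str, fmt: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or a MatrixMarket directory.

    ``fmt`` is inferred from the path when omitted: directories are treated as
    CellRanger MTX layouts, ``.csv``/``.csv.gz`` as CSV, anything else as TSV.
    """
    if fmt is None:
        if os.path.isdir(path):
            fmt = "mtx_dir"
        elif path.rstrip(".gz").endswith(".csv"):
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx_dir":
        mat = _read_mtx_dir(path)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        dupes = _duplicates(list(df.index))
        if dupes:
            raise MatrixFormatError(f"duplicate gene ids: {sorted(dupes)}")
        mat = ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))
    else:
        raise MatrixFormatError(f"unknown matrix format {fmt!r}")
    if transpose:
        mat = ExpressionMatrix(mat.values.T, mat.sample_ids, mat.gene_ids)
    return mat


def _read_mtx_dir(path: str) -> ExpressionMatrix:
    from scipy.io import mmread

    mtx = _first_existing(path, ["matrix.mtx", "matrix.mtx.gz"])
    feat = _first_existing(
        path, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"]
    )
    bar = _first_existing(path, ["barcodes.tsv", "barcodes.tsv.gz"])
    values = np.asarray(mmread(mtx).todense(), dtype=float)
    genes = pd.read_csv(feat, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    samples = pd.read_csv(bar, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if values.shape != (len(genes), len(samples)):
        raise MatrixFormatError(
            f"mtx shape {values.shape} does not match "
            f"{len(genes)} features x {len(samples)} barcodes"
        )
    return ExpressionMatrix(values, genes, samples)


def _first_existing(directory: str, names: list[str]) -> str:
    for name in names:
        cand = os.path.join(directory, name)
        if os.path.exists(cand):
            return cand
    raise MatrixFormatError(f"none of {names} found in {directory}")


def write_matrix(matrix: ExpressionMatrix, path: str) -> None:
    """Write a matrix as TSV (gene ids in the first column, sample header)."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t")


def read_classes(path: str) -> dict[str, str]:
    """Read a two-column (sample, class) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixFormatError("classes file needs two columns: sample, class")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# result tables

_SELECTION_HEAD = ["gene", "best_model", "n_peaks", "adequate", "transform"]
_DE_HEAD = [
    "gene", "peak", "class_name", "overlap", "peak_size",
    "class_size", "population", "p_value", "fdr",
]


def _fmt(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _params_to_string(params_dict: dict) -> str:
    parts = []
    for k, v in params_dict.items():
        if isinstance(v, list):
            parts.append(f"{k}={','.join(f'{x:.6g}' for x in v)}")
        else:
            parts.append(f"{k}={v:.6g}")
    return ";".join(parts)


def params_from_string(s: str):
    """Parse a semicolon-joined key=value parameter string back to ModelParams."""
    from .distributions import ModelParams

    kw = {}
    if s and s != "NA":
        for part in s.split(";"):
            k, v = part.split("=", 1)
            if "," in v or k in ("weights", "mus", "sigmas"):
                kw[k] = [float(x) for x in v.split(",")]
            else:
                kw[k] = float(v)
    return ModelParams(**kw)


def write_results(results, path: str) -> None:
    """Write selection or DE results as a deterministic TSV.

    Floats carry 6 significant digits; empty result lists still produce the
    header.  Selection tables get one p/FDR/params column triple per model.
    """
    from .detest import DETestResult
    from .distributions import ModelName

    try:
        handle = open(path, "w")
    except OSError as exc:
        raise MatrixFormatError(f"cannot write {path}: {exc}") from exc
    with handle:
        if results and isinstance(results[0], DETestResult):
            handle.write("\t".join(_DE_HEAD) + "\n")
            for r in results:
                handle.write(
                    "\t".join(
                        _fmt(getattr(r, c)) for c in _DE_HEAD
                    )
                    + "\n"
                )
            return
        cols = list(_SELECTION_HEAD)
        for m in ModelName:
            cols += [f"{m.value}_ks_p", f"{m.value}_ks_fdr", f"{m.value}_params"]
        handle.write("\t".join(cols) + "\n")
        for r in results:
            row = [
                r.gene,
                r.best_model.value if r.best_model is not None else "NA",
                str(r.n_peaks),
                str(r.adequate),
                r.transform,
            ]
            for m in ModelName:
                fit = r.fits.get(m)
                if fit is None:
                    row += ["NA", "NA", "NA"]
                else:
                    row += [
                        _fmt(float(fit.ks_pvalue)),
                        _fmt(float(fit.ks_fdr)),
                        _params_to_string(fit.params.as_dict(m)),
                    ]
            handle.write("\t".join(row) + "\n")


def read_selection(path: str):
    """Read a selection TSV back into (partial) SelectionResult objects.

    Only the best model's fit is reconstructed (enough to assign peaks for
    the DE test); log-likelihoods are not serialized.
    """
    from .distributions import ModelFit, ModelName
    from .select import SelectionResult

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        best = row["best_model"]
        fits = {}
        best_model = None
        if best != "NA" and isinstance(best, str):
            best_model = ModelName(best)
            params = params_from_string(row.get(f"{best}_params", ""))
            ncomp = params.n_components
            fit = ModelFit(
                model=best_model, params=params, loglik=float("nan"),
                n_components=ncomp, converged=True,
            )
            try:
                fit.ks_pvalue = float(row[f"{best}_ks_p"])
                fit.ks_fdr = float(row[f"{best}_ks_fdr"])
            except (KeyError, ValueError):
                pass
            fits[best_model] = fit
        out.append(
            SelectionResult(
                gene=str(row["gene"]),
                best_model=best_model,
                fits=fits,
                n_peaks=int(row["n_peaks"]),
                adequate=str(row["adequate"]) == "True",
                transform=str(row.get("transform", "identity")),
            )
        )
    return out
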