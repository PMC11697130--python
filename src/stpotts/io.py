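"""Reading, writing and preprocessing of expression matrices and coordinates.

Dense matrices are comma- or tab-delimited text with a header row and an id
column; sparse counts are Matrix Market (.mtx) with sidecar gene/barcode
files. Preprocessing follows the standard single-cell recipe: library-size
normalization to the median total count, log(1 + x), gene centering, PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

__all__ = [
    "ExpressionMatrix",
    "CellCoordinates",
    "PCMatrix",
    "read_expression",
    "write_expression",
    "read_coordinates",
    "write_coordinates",
    "read_labels",
    "write_labels",
    "preprocess_to_pcs",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with aligned identifiers."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list
    is_count: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lists must match matrix dimensions")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values.astype(float))):
            raise ValueError("expression matrix contains missing or non-finite entries")
        if self.is_count:
            v = self.values
            if np.any(v < 0) or np.any(v != np.round(v)):
                raise ValueError("count matrix must hold nonnegative integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class CellCoordinates:
    """n x 2 spatial coordinates aligned to an ExpressionMatrix row order."""

    xy: np.ndarray
    cell_ids: list

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must be an n x 2 matrix")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.cell_ids) != self.xy.shape[0]:
            raise ValueError("cell_ids must match the number of rows")

    @property
    def n(self) -> int:
        return self.xy.shape[0]


@dataclass
class PCMatrix:
    """H x n matrix of principal-component scores, Y[h, i] = PC h of cell i."""

    Y: np.ndarray
    explained_variance: np.ndarray | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[0] < 1 or self.Y.shape[1] < 2:
            raise ValueError("Y must be an H x n matrix with H >= 1, n >= 2")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("PC matrix contains non-finite entries")

    @property
    def H(self) -> int:
        return self.Y.shape[0]

    @property
    def n(self) -> int:
        return self.Y.shape[1]


def _read_table(path):
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc


def read_expression(path, format: str = "dense", *, orientation: str | None = None,
                    genes_path=None, cells_path=None, is_count: bool | None = None
                    ) -> ExpressionMatrix:
    """Read an expression matrix; the result is always cells x genes.

    Parameters
    ----------
    format : {"dense", "csv", "mtx", "matrix-market"}
        Dense delimited text (header row + id column) or Matrix Market with
        sidecar id files.
    orientation : {"cells-by-genes", "genes-by-cells"}, optional
        Layout of the *stored* matrix. Defaults to cells-by-genes for dense
        text and genes-by-cells for Matrix Market (the single-cell
        convention).
    genes_path, cells_path
        Sidecar one-id-per-line files, required for the sparse format.
    is_count
        Override count-ness; by default inferred from integrality.
    """
    if format in {"dense", "csv", "tsv", "dense-delimited"}:
        orientation = orientation or "cells-by-genes"
        df = _read_table(path)
        values = df.to_numpy()
        if orientation == "genes-by-cells":
            values = values.T
            gene_ids = [str(i) for i in df.index]
            cell_ids = [str(c) for c in df.columns]
        else:
            cell_ids = [str(i) for i in df.index]
            gene_ids = [str(c) for c in df.columns]
    elif format in {"mtx", "matrix-market"}:
        orientation = orientation or "genes-by-cells"
        if genes_path is None or cells_path is None:
            raise ValueError("matrix-market input needs genes_path and cells_path sidecars")
        values = np.asarray(mmread(path).todense())
        gene_ids = Path(genes_path).read_text().split()
        cell_ids = Path(cells_path).read_text().split()
        if orientation == "genes-by-cells":
            values = values.T
    else:
        raise ValueError(f"unknown format {format!r}")
    if orientation not in {"cells-by-genes", "genes-by-cells"}:
        raise ValueError(f"unknown orientation {orientation!r}")

    if values.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {values.shape} does not align with "
            f"{len(cell_ids)} cell ids and {len(gene_ids)} gene ids"
        )
    if is_count is None:
        v = values.astype(float)
        is_count = bool(np.all(v >= 0) and np.all(v == np.round(v)))
    return ExpressionMatrix(values, cell_ids, gene_ids, is_count=is_count)


def write_expression(expr: ExpressionMatrix, path, format: str = "dense", *,
                     genes_path=None, cells_path=None) -> None:
    if format in {"dense", "csv", "dense-delimited"}:
        pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids).to_csv(path)
    elif format in {"mtx", "matrix-market"}:
        if genes_path is None or cells_path is None:
            raise ValueError("matrix-market output needs genes_path and cells_path")
        mmwrite(str(path), csr_matrix(expr.values.T))  # genes x cells convention
        Path(genes_path).write_text("\n".join(map(str, expr.gene_ids)) + "\n")
        Path(cells_path).write_text("\n".join(map(str, expr.cell_ids)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_coordinates(path, cell_ids=None) -> CellCoordinates:
    """Read an id,x,y table; reorder rows to ``cell_ids`` if given."""
    df = _read_table(path)
    if df.shape[1] != 2:
        raise ValueError(f"expected two coordinate columns, found {df.shape[1]}")
    xy = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = df.index[~np.all(np.isfinite(xy), axis=1)].tolist()
        raise ValueError(f"non-finite coordinates for cells {bad}")
    ids = [str(i) for i in df.index]
    if cell_ids is not None:
        cell_ids = [str(i) for i in cell_ids]
        lookup = {c: r for r, c in enumerate(ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing or len(cell_ids) != len(ids):
            raise ValueError(f"coordinate ids do not align with expression ids: missing {missing[:5]}")
        xy = xy[[lookup[c] for c in cell_ids]]
        ids = list(cell_ids)
    return CellCoordinates(xy, ids)


def write_coordinates(coords: CellCoordinates, path) -> None:
    pd.DataFrame(coords.xy, index=coords.cell_ids, columns=["x", "y"]).to_csv(path)


def read_labels(path, cell_ids=None) -> np.ndarray:
    df = _read_table(path)
    labels = df.iloc[:, 0]
    if cell_ids is not None:
        labels = labels.reindex([str(i) for i in cell_ids])
        if labels.isna().any():
            raise ValueError("label ids do not align with the requested cell ids")
    return labels.to_numpy()


def write_labels(labels, cell_ids, path) -> None:
    pd.DataFrame({"label": np.asarray(labels)}, index=list(cell_ids)).rename_axis("cell_id").to_csv(path)


def normalize_counts(values: np.ndarray, target: float | None = None) -> np.ndarray:
    """Scale each cell's counts to a common library size (median total)."""
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0).tolist()
        raise ValueError(f"cells with zero total count cannot be normalized: rows {bad}")
    if target is None:
        target = float(np.median(totals))
    return values * (target / totals)[:, None]


def preprocess_to_pcs(expr: ExpressionMatrix, H: int = 50, *,
                      do_normalize: bool = True, do_log: bool = True,
                      scale_genes: bool = False, gene_subset=None) -> PCMatrix:
    """normalize -> log(1+x) -> center -> PCA, returning the top-H PC scores.

    The returned matrix is H x n with components ordered by decreasing
    explained variance. Each component's sign is fixed so that its
    largest-absolute gene loading is positive, making the output
    deterministic across linear-algebra backends.
    """
    import warnings

    values = expr.values.astype(float)
    if gene_subset is not None:
        col = {g: j for j, g in enumerate(expr.gene_ids)}
        values = values[:, [col[g] for g in gene_subset]]
    n, G = values.shape
    if not 1 <= H <= min(n - 1, G):
        raise ValueError(f"H must lie in [1, min(n-1, G)] = [1, {min(n - 1, G)}]")
    if (do_normalize or do_log) and not expr.is_count:
        warnings.warn("normalize/log requested on non-count data; applying anyway",
                      stacklevel=2)
    if do_normalize:
        values = normalize_counts(values)
    if do_log:
        values = np.log1p(values)

    X = values - values.mean(axis=0)
    if scale_genes:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S.size == 0 or S[0] == 0.0:
        # fully degenerate input (all processed cells identical): every PC
        # score is exactly zero
        return PCMatrix(np.zeros((H, n)), explained_variance=np.zeros(H))
    rank = int(np.sum(S > S[0] * 1e-12))
    if H > rank:
        raise ValueError(f"H={H} exceeds the matrix rank; at most {rank} components available")
    scores = U[:, :H] * S[:H]
    loadings = Vt[:H]
    # Deterministic sign: largest-|loading| entry of each component positive.
    flip = np.sign(loadings[np.arange(H), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    explained = (S[:H] ** 2) / (n - 1)
    return PCMatrix(scores.T, explained_variance=explained)
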