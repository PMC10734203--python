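"""Core expression-matrix containers, file I/O, normalization and gene selection.

Everything downstream (similarity search, k-NN regression, cross-validation,
pattern discovery) operates on :class:`ExpressionMatrix`, a thin cells x genes
container with explicit identifiers. All cross-matrix alignment goes through
explicit gene-id joins, never positional indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "SpatialQuery",
    "SubReference",
    "GeneSparsity",
    "read_matrix",
    "write_matrix",
    "read_coords",
    "write_coords",
    "log_normalize",
    "shared_genes",
    "gene_sparsity",
    "hvg_ranking",
    "select_hvg_union",
]


class DataValidationError(ValueError):
    """Raised when a matrix or its identifiers violate the container contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with row/column identifiers.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` array of non-negative reals. Raw counts
        or log-normalized units depending on ``normalized``.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    normalized
        Whether values are on the log-normalized scale (see
        :func:`log_normalize`).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise DataValidationError("values must be 2-D (cells x genes)")
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise DataValidationError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.gene_ids) != p:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene ids for {p} columns"
            )
        for label, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
                raise DataValidationError(
                    f"duplicate {label} identifiers: {list(dupes)[:5]}"
                )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("values contain non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Positional indices of ``genes`` (all must be present)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=np.intp)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[:, idx], self.cell_ids, np.asarray(genes, dtype=object),
            normalized=self.normalized,
        )

    def subset_cells(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            self.values[rows], self.cell_ids[rows], self.gene_ids,
            normalized=self.normalized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cell_ids),
                            columns=list(self.gene_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool = False
                       ) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64),
                   np.asarray(df.index, dtype=object),
                   np.asarray(df.columns, dtype=object),
                   normalized=normalized)


@dataclass
class SpatialQuery:
    """A spatial expression matrix plus per-cell 2-D coordinates."""

    expr: ExpressionMatrix
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataValidationError("coords must be (n_cells, 2)")
        if self.coords.shape[0] != self.expr.n_cells:
            raise DataValidationError("coords row count != cell count")
        if not np.all(np.isfinite(self.coords)):
            raise DataValidationError("coords contain non-finite entries")


@dataclass
class SubReference:
    """One partition of a reference, split into shared and unique gene blocks.

    ``shared`` carries the genes common to the query and all references (in
    canonical order); ``unique`` carries the prediction-target genes this
    sub-reference can contribute to. Both blocks share identical cell rows.
    """

    shared: ExpressionMatrix
    unique: ExpressionMatrix
    origin: str
    index: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.shared.cell_ids, self.unique.cell_ids):
            raise DataValidationError(
                "shared and unique blocks must have identical cell ids"
            )

    @property
    def n_cells(self) -> int:
        return self.shared.n_cells


@dataclass(frozen=True)
class GeneSparsity:
    gene_id: str
    sparsity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsity <= 1.0:
            raise DataValidationError("sparsity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "mtx", "h5ad")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".h5ad", ".h5"):
        return "h5ad"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_matrix(path: str | Path, format: str | None = None,
                genes_in_rows: bool = False, normalized: bool = False
                ) -> ExpressionMatrix:
    """Read an expression matrix from CSV, MatrixMarket or an h5ad container.

    CSV: header row of gene ids, first column of cell ids. MatrixMarket: a
    ``.mtx`` triplet file with sibling ``genes.tsv`` / ``barcodes.tsv`` id
    files. h5ad: the AnnData layout (``X``, ``obs_names``, ``var_names``).
    Set ``genes_in_rows=True`` for genes x cells dumps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    if fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        try:
            df = pd.read_csv(path, index_col=0, sep=sep)
        except (pd.errors.ParserError, UnicodeDecodeError) as exc:
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        if genes_in_rows:
            df = df.T
        return ExpressionMatrix.from_dataframe(df, normalized=normalized)

    if fmt == "mtx":
        import scipy.io as sio
        try:
            mat = sio.mmread(path)
        except ValueError as exc:
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        genes = pd.read_csv(path.parent / "genes.tsv", header=None, sep="\t")[0]
        cells = pd.read_csv(path.parent / "barcodes.tsv", header=None, sep="\t")[0]
        values = np.asarray(sp.csr_matrix(mat).todense())
        if genes_in_rows:
            values = values.T
        return ExpressionMatrix(values, cells.to_numpy(object),
                                genes.to_numpy(object), normalized=normalized)

    # h5ad
    import anndata as ad
    adata = ad.read_h5ad(path)
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    values = np.asarray(X, dtype=np.float64)
    if genes_in_rows:
        values = values.T
        return ExpressionMatrix(values, adata.var_names.to_numpy(object),
                                adata.obs_names.to_numpy(object),
                                normalized=normalized)
    return ExpressionMatrix(values, adata.obs_names.to_numpy(object),
                            adata.var_names.to_numpy(object),
                            normalized=normalized)


def write_matrix(m: ExpressionMatrix, path: str | Path,
                 format: str | None = None) -> None:
    """Write a matrix in any of the supported formats (inverse of read)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        m.to_dataframe().to_csv(path, sep=sep)
    elif fmt == "mtx":
        import scipy.io as sio
        sio.mmwrite(str(path), sp.coo_matrix(m.values))
        pd.Series(list(m.gene_ids)).to_csv(path.parent / "genes.tsv",
                                           header=False, index=False)
        pd.Series(list(m.cell_ids)).to_csv(path.parent / "barcodes.tsv",
                                           header=False, index=False)
    elif fmt == "h5ad":
        import anndata as ad
        adata = ad.AnnData(X=m.values.copy())
        adata.obs_names = [str(c) for c in m.cell_ids]
        adata.var_names = [str(g) for g in m.gene_ids]
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_coords(path: str | Path, cell_ids: Sequence[str] | None = None
                ) -> np.ndarray:
    """Read per-cell 2-D coordinates from a CSV keyed by cell id.

    If ``cell_ids`` is given the rows are re-ordered to match it.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 2:
        raise ValueError(f"coordinate file must have 2 columns, got {df.shape[1]}")
    if cell_ids is not None:
        missing = set(map(str, cell_ids)) - set(map(str, df.index))
        if missing:
            raise ValueError(f"coordinates missing for cells: {sorted(missing)[:5]}")
        df = df.loc[[str(c) for c in cell_ids]]
    return df.to_numpy(dtype=np.float64)


def write_coords(coords: np.ndarray, cell_ids: Sequence[str],
                 path: str | Path) -> None:
    pd.DataFrame(coords, index=list(cell_ids), columns=["x", "y"]).to_csv(path)


# ---------------------------------------------------------------------------
# normalization / gene selection
# ---------------------------------------------------------------------------

def log_normalize(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize each cell and log-transform.

    Each cell's counts are divided by that cell's total, multiplied by
    ``scale`` (default 1e4) and passed through ``log(1 + x)`` — the standard
    LogNormalize transform. Zero maps to zero and within-cell proportions are
    preserved, so doubling every count of a cell leaves its normalized vector
    unchanged.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {list(m.cell_ids[zero[:5]])}"
        )
    values = np.log1p(m.values / totals[:, None] * scale)
    return ExpressionMatrix(values, m.cell_ids, m.gene_ids, normalized=True)


def shared_genes(query: ExpressionMatrix,
                 refs: Iterable[ExpressionMatrix]) -> list[str]:
    """Genes common to the query and *all* references, lexicographically sorted.

    This is the common-gene block used for neighbor search; an empty
    intersection is an error.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("at least one reference is required")
    common = set(query.gene_ids)
    for r in refs:
        common &= set(r.gene_ids)
    if not common:
        raise ValueError("query and references share no genes")
    return sorted(common)


def gene_sparsity(m: ExpressionMatrix) -> list[GeneSparsity]:
    """Per-gene fraction of cells with exactly zero expression."""
    frac = (m.values == 0).mean(axis=0)
    return [GeneSparsity(g, float(s)) for g, s in zip(m.gene_ids, frac)]


def hvg_ranking(m: ExpressionMatrix, n_bins: int = 20,
                method: str = "binned_dispersion") -> pd.Series:
    """Dispersion statistic per gene, higher = more variable.

    ``binned_dispersion`` (default): per-gene variance of the (log-scale)
    expression divided by the median variance of genes with similar mean
    expression (``n_bins`` equal-occupancy mean bins) — a vst-style
    normalized dispersion that removes the mean-variance trend.
    ``variance``: raw per-gene variance.
    """
    means = m.values.mean(axis=0)
    variances = m.values.var(axis=0)
    if method == "variance":
        disp = variances
    elif method == "binned_dispersion":
        order = np.argsort(means, kind="stable")
        n_bins_eff = max(1, min(n_bins, m.n_genes))
        bins = np.empty(m.n_genes, dtype=np.intp)
        bins[order] = np.arange(m.n_genes) * n_bins_eff // m.n_genes
        expected = np.ones(m.n_genes)
        for b in range(n_bins_eff):
            mask = bins == b
            med = np.median(variances[mask])
            expected[mask] = med if med > 0 else 1.0
        disp = variances / expected
    else:
        raise ValueError(f"unknown HVG method {method!r}")
    return pd.Series(disp, index=list(m.gene_ids)).sort_values(
        ascending=False, kind="stable")


def select_hvg_union(refs: Sequence[ExpressionMatrix], n_per_ref: int = 2000,
                     exclude: Iterable[str] | None = None,
                     method: str = "binned_dispersion") -> list[str]:
    """Union of each reference's top-``n_per_ref`` highly variable genes.

    ``exclude`` (typically the query's measured panel) removes genes from the
    result so that only candidate prediction targets remain. The returned
    list is lexicographically sorted.
    """
    union: set[str] = set()
    for r in refs:
        if n_per_ref > r.n_genes:
            warnings.warn(
                f"n_per_ref={n_per_ref} exceeds gene count {r.n_genes}; "
                "using all genes", stacklevel=2)
        ranking = hvg_ranking(r, method=method)
        union |= set(ranking.index[:n_per_ref])
    if exclude is not None:
        union -= set(exclude)
    return sorted(union)
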