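"""UMI count-matrix container, I/O, size factors, thinning and gene filtering.

The container is deliberately minimal: a dense non-negative integer matrix in
cells x genes orientation with string labels. Dense storage is appropriate for
the moderate matrices this package targets (design simulations and desk-scale
analyses); the 10x-style MatrixMarket reader densifies on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class CountParseError(ValueError):
    """Raised when an input file cannot be interpreted as a count matrix."""


def _as_count_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if scipy.sparse.issparse(values):
        arr = values.toarray()
    if arr.ndim != 2:
        raise ValueError(f"count matrix must be 2-D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)):
            raise ValueError("count matrix contains non-finite entries")
        rounded = np.rint(arr)
        if not np.array_equal(rounded, arr):
            bad = np.argwhere(rounded != arr)[0]
            raise ValueError(
                f"non-integer count at cell {bad[0]}, gene {bad[1]}: {arr[tuple(bad)]!r}"
            )
        arr = rounded
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"count matrix has non-numeric dtype {arr.dtype}")
    arr = arr.astype(np.int64, copy=False)
    if (arr < 0).any():
        bad = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative count at cell {bad[0]}, gene {bad[1]}")
    return arr


@dataclass
class CountMatrix:
    """Observed UMI counts Y_cg, cells x genes, with row/column labels."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_count_array(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell labels for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene labels for {n_genes} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene labels: {dupes[:5]}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell, N_c = sum_g Y_cg."""
        return self.values.sum(axis=1)

    def mean_reads_per_cell(self) -> np.ndarray:
        """Observed mean reads per cell for each gene (the filtering scale)."""
        return self.values.mean(axis=0)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from None

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(self.values[:, idx], self.cell_ids, [self.gene_ids[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class SizeFactors:
    """Per-cell size factors gamma_c (mean 1 over usable cells) and mean depth.

    ``n_reads`` is the mean total UMIs per cell; the per-cell Poisson scale is
    s_c = gamma_c * n_reads. Cells with zero totals have undefined gamma
    (stored NaN) and are excluded from estimation via ``usable``.
    """

    gamma: np.ndarray
    n_reads: float
    usable: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.usable is None:
            self.usable = np.isfinite(self.gamma) & (self.gamma > 0)
        self.usable = np.asarray(self.usable, dtype=bool)
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        g = self.gamma[self.usable]
        if g.size == 0:
            raise ValueError("no usable cells")
        if (g <= 0).any():
            raise ValueError("size factors of usable cells must be positive")
        if abs(g.mean() - 1.0) > 1e-9:
            raise ValueError(f"mean size factor is {g.mean()!r}, expected 1")

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def scales(self) -> np.ndarray:
        """Poisson scales s_c = gamma_c * n_reads for usable cells."""
        return self.gamma[self.usable] * self.n_reads


@dataclass(frozen=True)
class SubsampleSpec:
    """Binomial-thinning specification: keep each UMI with probability ``rate``."""

    rate: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.rate <= 1.0):
            raise ValueError(f"subsample rate must be in (0, 1], got {self.rate}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MTX_GENE_FILES = ("genes.tsv", "features.tsv")
_MTX_BARCODE_FILE = "barcodes.tsv"


def _read_label_file(path: str, column: int = 0) -> list[str]:
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            labels.append(parts[min(column, len(parts) - 1)])
    return labels


def load_counts(path: str, format: str | None = None,
                orientation: str = "cells_by_genes") -> CountMatrix:
    """Read a count matrix from MatrixMarket or dense CSV/TSV.

    MatrixMarket input follows the 10x v2 layout: the .mtx file stores
    genes x cells integer triplets, with ``genes.tsv`` (or ``features.tsv``)
    and ``barcodes.tsv`` next to it. Pass ``orientation='genes_by_cells'``
    for that layout; the result is always cells x genes.
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(ext)
        if format is None:
            raise CountParseError(f"cannot infer format from {path!r}")
    if format == "mtx":
        return _load_mtx(path, orientation)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise CountParseError(f"failed to parse {path!r}: {exc}") from exc
        values, rows, cols = df.to_numpy(), list(df.index), list(df.columns)
        if orientation == "genes_by_cells":
            values, rows, cols = values.T, cols, rows
        try:
            return CountMatrix(values, rows, cols)
        except ValueError as exc:
            raise CountParseError(f"{path!r}: {exc}") from exc
    raise ValueError(f"unknown format {format!r}")


def _load_mtx(path: str, orientation: str) -> CountMatrix:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise CountParseError(f"failed to parse MatrixMarket file {path!r}: {exc}") from exc
    dirname = os.path.dirname(os.path.abspath(path))
    gene_path = None
    for candidate in _MTX_GENE_FILES:
        p = os.path.join(dirname, candidate)
        if os.path.exists(p):
            gene_path = p
            break
    barcode_path = os.path.join(dirname, _MTX_BARCODE_FILE)
    if gene_path is None or not os.path.exists(barcode_path):
        raise CountParseError(
            f"companion label files (genes.tsv/features.tsv + barcodes.tsv) "
            f"not found next to {path!r}"
        )
    # 10x genes.tsv may carry id + symbol columns; keep the first (unique id).
    genes = _read_label_file(gene_path, column=0)
    barcodes = _read_label_file(barcode_path, column=0)
    values = mat.toarray() if scipy.sparse.issparse(mat) else np.asarray(mat)
    rows, cols = (genes, barcodes) if orientation == "genes_by_cells" else (barcodes, genes)
    if values.shape[0] != len(rows) or values.shape[1] != len(cols):
        raise CountParseError(
            f"{path!r}: matrix is {values.shape}, labels are "
            f"({len(rows)}, {len(cols)})"
        )
    if orientation == "genes_by_cells":
        values = values.T
        rows, cols = cols, rows
    try:
        return CountMatrix(values, rows, cols)
    except ValueError as exc:
        raise CountParseError(f"{path!r}: {exc}") from exc


def write_counts(counts: CountMatrix, path: str, format: str | None = None) -> None:
    """Write a count matrix as dense CSV/TSV or 10x-style MatrixMarket.

    MTX output uses the 10x v2 layout (genes x cells) with ``genes.tsv`` and
    ``barcodes.tsv`` companions written next to the .mtx file.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        counts.to_frame().to_csv(path, sep=sep)
        return
    if format == "mtx":
        dirname = os.path.dirname(os.path.abspath(path))
        sparse = scipy.sparse.coo_matrix(counts.values.T)  # genes x cells
        scipy.io.mmwrite(path, sparse, field="integer")
        with open(os.path.join(dirname, "genes.tsv"), "w") as fh:
            for g in counts.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(os.path.join(dirname, _MTX_BARCODE_FILE), "w") as fh:
            for c in counts.cell_ids:
                fh.write(f"{c}\n")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Size factors, thinning, filtering
# ---------------------------------------------------------------------------

def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """Estimate gamma_c = N_c / mean(N_c) and n_reads = mean(N_c).

    With this normalization mean(gamma) = 1 over usable cells, so that
    s_c = gamma_c * n_reads equals each cell's expected total count under the
    Poisson model. Cells with zero totals get gamma = NaN and are excluded
    from downstream estimation.
    """
    totals = counts.cell_totals().astype(float)
    usable = totals > 0
    if not usable.any():
        raise ValueError("no usable cells: all cell totals are zero")
    n_reads = float(totals[usable].mean())
    gamma = np.where(usable, totals / n_reads, np.nan)
    return SizeFactors(gamma=gamma, n_reads=n_reads, usable=usable)


def thin_counts(counts: CountMatrix, spec: SubsampleSpec) -> CountMatrix:
    """Binomial thinning: each entry becomes Binomial(Y_cg, rate).

    Thinning a Poisson(s*x) count at rate q yields Poisson(q*s*x), so this maps
    the generative model at depth s exactly to the same model at depth q*s.
    Draws are made entry-by-entry in row-major order from a single seeded
    generator, so results are reproducible for a fixed seed.
    """
    if spec.rate == 1.0:
        return CountMatrix(counts.values.copy(), counts.cell_ids, counts.gene_ids)
    rng = np.random.default_rng(spec.seed)
    thinned = rng.binomial(counts.values, spec.rate)
    return CountMatrix(thinned, counts.cell_ids, counts.gene_ids)


def filter_genes(counts: CountMatrix, stats=None, min_mean_reads: float = 0.0,
                 min_eb_variance: float | None = None) -> CountMatrix:
    """Keep genes with mean observed reads/cell >= ``min_mean_reads`` and,
    when requested, EB-estimated variance > ``min_eb_variance``.

    ``stats`` (a GeneStatistics) is required only for the variance filter and
    must cover exactly the same genes. Cell set and gene order are preserved.
    """
    keep = counts.mean_reads_per_cell() >= min_mean_reads
    if min_eb_variance is not None:
        if stats is None:
            raise ValueError("variance filter requires gene statistics")
        if list(stats.gene_ids) != list(counts.gene_ids):
            raise ValueError("gene statistics were computed on a different gene set")
        var_eb = np.where(np.isfinite(stats.var_eb), stats.var_eb, -np.inf)
        keep &= var_eb > min_eb_variance
    idx = np.flatnonzero(keep)
    return CountMatrix(counts.values[:, idx], counts.cell_ids,
                       [counts.gene_ids[i] for i in idx])
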