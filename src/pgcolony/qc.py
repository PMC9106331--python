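"""Single-cell RNA-seq count-matrix quality control.

One small operation: filter a genes x cells count matrix by per-cell
library size (excluding empty droplets and doublets), mitochondrial
fraction, and gene prevalence — genes expressed in *fewer than*
``min_cells_per_gene`` of the retained cells are removed (a gene present in
exactly the threshold number of cells is kept).  Filters apply in that
order.  Default bounds are data-driven (barcode-rank knee for library
size, median + 3 MAD for the mitochondrial fraction) and overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["CountMatrix", "QCReport", "qc_filter_counts", "read_counts_mtx", "write_counts_mtx"]


@dataclass
class CountMatrix:
    """Genes x cells integer counts with unique identifiers."""

    counts: sp.csr_matrix            # genes x cells
    genes: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = np.asarray(self.genes)
        self.barcodes = np.asarray(self.barcodes)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("counts shape does not match identifier lengths")
        if len(set(self.genes)) != len(self.genes) or len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("gene and barcode identifiers must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction(self, prefix: str = "MT-") -> np.ndarray:
        is_mito = np.char.startswith(self.genes.astype(str), prefix)
        lib = self.library_sizes()
        mito = np.asarray(self.counts[is_mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
        return frac

    @classmethod
    def from_dense(cls, frame: pd.DataFrame) -> "CountMatrix":
        """Dense genes-by-cells DataFrame (index = genes, columns = cells)."""
        return cls(sp.csr_matrix(frame.to_numpy()), frame.index.to_numpy(), frame.columns.to_numpy())

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.genes, columns=self.barcodes)


@dataclass
class QCReport:
    cells_before: int
    cells_after: int
    genes_before: int
    genes_after: int
    lib_size_bounds: tuple[float, float]
    mito_max: float
    min_cells_per_gene: int


def _knee_lower_bound(lib: np.ndarray) -> float:
    """Barcode-rank knee: the point of maximum distance to the chord of the
    log-log rank curve; returns the library size at the knee."""
    lib = np.sort(lib[lib > 0])[::-1]
    if len(lib) < 3:
        return 0.0
    x = np.log10(np.arange(1, len(lib) + 1))
    y = np.log10(lib)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    seg = p1 - p0
    seg_len = np.hypot(*seg)
    if seg_len == 0:
        return 0.0
    d = np.abs(seg[0] * (p0[1] - y) - (p0[0] - x) * seg[1]) / seg_len
    return float(lib[int(np.argmax(d))])


def qc_filter_counts(
    matrix: CountMatrix,
    lib_size_bounds: tuple[float, float] | None = None,
    mito_max: float | None = None,
    min_cells_per_gene: int = 50,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, QCReport]:
    """Filter cells by library size and mitochondrial fraction, then genes
    by prevalence among the retained cells.

    Returns the filtered matrix and a QC report.  An empty result is a
    warning, not an error.  The operation is idempotent: applying it twice
    with the same resolved bounds equals applying it once.
    """
    g0, c0 = matrix.shape
    lib = matrix.library_sizes()

    if lib_size_bounds is None:
        lower = _knee_lower_bound(lib)
        upper = float(np.inf)
        lib_size_bounds = (lower, upper)
    lo, hi = lib_size_bounds
    if lo > hi:
        raise ValueError("library-size bounds must be well-ordered")
    keep_cells = (lib >= lo) & (lib <= hi)

    mito = matrix.mito_fraction(mito_prefix)
    if mito_max is None:
        med = float(np.median(mito[keep_cells])) if keep_cells.any() else 0.0
        mad = float(np.median(np.abs(mito[keep_cells] - med))) if keep_cells.any() else 0.0
        mito_max = med + 3.0 * 1.4826 * mad
    keep_cells &= mito <= mito_max

    sub = matrix.counts[:, keep_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene  # strictly "fewer than" removed

    out = CountMatrix(sub[keep_genes], matrix.genes[keep_genes], matrix.barcodes[keep_cells])
    if out.shape[0] == 0 or out.shape[1] == 0:
        logger.warning("QC filtering left an empty matrix (%d genes, %d cells)", *out.shape)
    report = QCReport(
        cells_before=c0,
        cells_after=int(keep_cells.sum()),
        genes_before=g0,
        genes_after=int(keep_genes.sum()),
        lib_size_bounds=(float(lo), float(hi)),
        mito_max=float(mito_max),
        min_cells_per_gene=int(min_cells_per_gene),
    )
    return out, report


def read_counts_mtx(prefix: str | Path) -> CountMatrix:
    """Read MTX triple ``<prefix>.mtx`` / ``<prefix>_genes.tsv`` /
    ``<prefix>_barcodes.tsv``."""
    import scipy.io

    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    genes = np.loadtxt(str(prefix) + "_genes.tsv", dtype=str, ndmin=1)
    barcodes = np.loadtxt(str(prefix) + "_barcodes.tsv", dtype=str, ndmin=1)
    return CountMatrix(counts, genes, barcodes)


def write_counts_mtx(matrix: CountMatrix, prefix: str | Path) -> None:
    import scipy.io

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(matrix.counts))
    np.savetxt(str(prefix) + "_genes.tsv", matrix.genes, fmt="%s")
    np.savetxt(str(prefix) + "_barcodes.tsv", matrix.barcodes, fmt="%s")
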