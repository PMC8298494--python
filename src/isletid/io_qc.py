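"""Count-matrix containers, 10x-style I/O, cell quality control and log-normalization.

The single-cell branch of the pipeline starts from a UMI count matrix
(genes x cells). Cells are filtered on three joint criteria — minimum
detected genes, minimum total UMIs, maximum mitochondrial UMI fraction —
with inclusive thresholds, and then normalized per cell as

    value(g, c) = ln(1 + scale_factor * count(g, c) / total(c))

with a scale factor of 10,000 (natural-log convention; the downstream
log-fold-change floor of 0.5 is interpreted on this scale).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCConfig",
    "QCReport",
    "NormalizedMatrix",
    "FormatError",
    "EmptyResultError",
    "read_counts",
    "write_counts",
    "read_cell_meta",
    "qc_filter",
    "log_normalize",
]

DEFAULT_MITO_PREFIXES = ("mt-", "MT-")


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


class EmptyResultError(ValueError):
    """Raised when a filtering step would leave no cells."""


@dataclass
class CountMatrix:
    """Genes x cells (or genes x samples) non-negative integer counts.

    Parameters
    ----------
    counts
        Sparse genes x cells matrix of raw UMI (or read) counts.
    gene_meta
        Per-gene table indexed by unique gene name, with a boolean
        ``mito`` column flagging mitochondrial genes.
    cell_meta
        Per-cell table indexed by unique barcode / sample id. May carry
        ``replicate``, ``fraction`` (sorted-fraction flag) and
        ``cluster`` columns.
    """

    counts: sp.spmatrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.gene_meta)} genes, {len(self.cell_meta)} cells)"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be non-negative integers")
        if not self.gene_meta.index.is_unique:
            raise FormatError("gene names must be unique")
        if not self.cell_meta.index.is_unique:
            raise FormatError("cell/sample ids must be unique")
        if "mito" not in self.gene_meta.columns:
            self.gene_meta = self.gene_meta.assign(mito=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def total_umis(self) -> np.ndarray:
        """Per-cell total UMI counts (library sizes)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Per-cell number of genes with at least one count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of UMIs from mitochondrial genes.

        Computed on raw counts; cells with zero total get fraction 0.
        """
        totals = self.total_umis().astype(float)
        mito_mask = self.gene_meta["mito"].to_numpy(dtype=bool)
        mito = np.asarray(self.counts[mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            counts=self.counts[:, mask],
            gene_meta=self.gene_meta,
            cell_meta=self.cell_meta.iloc[mask]
            if mask.dtype == bool
            else self.cell_meta.iloc[mask],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            counts=self.counts[mask, :],
            gene_meta=self.gene_meta.iloc[mask],
            cell_meta=self.cell_meta,
        )

    def row(self, gene: str) -> np.ndarray:
        """Dense count vector of one gene across cells."""
        i = self.gene_meta.index.get_loc(gene)
        return np.asarray(self.counts[i, :].todense()).ravel()


@dataclass
class QCConfig:
    """Cell-level quality thresholds (all inclusive)."""

    min_features: int = 500
    min_umis: int = 1000
    max_mito_frac: float = 0.07

    def __post_init__(self) -> None:
        if self.min_features < 0 or self.min_umis < 0 or self.max_mito_frac < 0:
            raise ValueError("QC thresholds must be >= 0")
        if self.max_mito_frac > 1:
            raise ValueError("max_mito_frac must be <= 1")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_fail_features: int
    n_fail_umis: int
    n_fail_mito: int


@dataclass
class NormalizedMatrix:
    """Log-normalized expression on the natural-log scale.

    Zeros stay exactly zero; nonzero values are ln(1 + sf * count / total).
    """

    values: sp.spmatrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame
    scale_factor: float
    cell_totals: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)

    @property
    def gene_names(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        i = self.gene_meta.index.get_loc(gene)
        return np.asarray(self.values[i, :].todense()).ravel()

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        return NormalizedMatrix(
            values=self.values[:, mask],
            gene_meta=self.gene_meta,
            cell_meta=self.cell_meta.iloc[mask],
            scale_factor=self.scale_factor,
            cell_totals=None if self.cell_totals is None else self.cell_totals[mask],
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_counts(
    matrix_path: str,
    features_path: str,
    barcodes_path: str,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
) -> CountMatrix:
    """Read a 10x-style MTX triplet into a :class:`CountMatrix`.

    The features file may have one column (gene name) or several
    tab-separated columns, in which case the first column is used.
    Mitochondrial genes are flagged by name prefix (default ``mt-``/``MT-``).
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed MTX
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    features = [line.split("\t")[0] for line in _read_lines(features_path)]
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    if mat.shape[0] != len(features):
        raise FormatError(
            f"MTX declares {mat.shape[0]} genes but features file has {len(features)} lines"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX declares {mat.shape[1]} cells but barcodes file has {len(barcodes)} lines"
        )
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise FormatError("MTX contains non-integer entries")
    gene_meta = pd.DataFrame(index=pd.Index(features, name="gene"))
    gene_meta["mito"] = [any(g.startswith(p) for p in mito_prefixes) for g in features]
    cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CountMatrix(counts=mat.tocsr().astype(np.int64), gene_meta=gene_meta, cell_meta=cell_meta)


def write_counts(m: CountMatrix, out_dir: str) -> dict[str, str]:
    """Write the MTX triplet plus a cell-metadata TSV into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "features": os.path.join(out_dir, "features.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "cell_meta": os.path.join(out_dir, "cell_meta.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(m.counts), field="integer")
    with open(paths["features"], "w") as fh:
        for g in m.gene_names:
            fh.write(f"{g}\n")
    with open(paths["barcodes"], "w") as fh:
        for b in m.cell_ids:
            fh.write(f"{b}\n")
    m.cell_meta.to_csv(paths["cell_meta"], sep="\t", index_label="barcode")
    return paths


def read_cell_meta(m: CountMatrix, meta_path: str) -> CountMatrix:
    """Attach a cell-metadata TSV (columns: barcode, replicate, fraction, cluster)."""
    meta = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str}).set_index("barcode")
    missing = m.cell_ids.difference(meta.index)
    if len(missing):
        raise FormatError(f"{len(missing)} barcodes missing from metadata (e.g. {missing[0]})")
    merged = m.cell_meta.join(meta.loc[m.cell_ids], how="left")
    return CountMatrix(counts=m.counts, gene_meta=m.gene_meta, cell_meta=merged)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(m: CountMatrix, q: QCConfig | None = None) -> tuple[CountMatrix, QCReport]:
    """Keep cells passing all three quality criteria jointly.

    A cell is retained iff detected genes >= ``min_features`` AND total
    UMIs >= ``min_umis`` AND mitochondrial fraction <= ``max_mito_frac``
    (boundaries inclusive). Genes are untouched. The report counts, per
    criterion, how many input cells fail it (a cell can fail several).
    """
    if q is None:
        q = QCConfig()
    n_feat = m.detected_genes()
    n_umi = m.total_umis()
    mito = m.mito_fraction()
    ok_feat = n_feat >= q.min_features
    ok_umi = n_umi >= q.min_umis
    ok_mito = mito <= q.max_mito_frac
    keep = ok_feat & ok_umi & ok_mito
    report = QCReport(
        n_input=m.n_cells,
        n_retained=int(keep.sum()),
        n_fail_features=int((~ok_feat).sum()),
        n_fail_umis=int((~ok_umi).sum()),
        n_fail_mito=int((~ok_mito).sum()),
    )
    if report.n_retained == 0:
        raise EmptyResultError("no cells pass the QC thresholds")
    return m.subset_cells(keep), report


def log_normalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell log-normalization: ln(1 + scale_factor * count / cell total).

    Operates column-wise on the sparse structure; zeros remain zero, so
    the sparsity pattern is preserved.
    """
    totals = m.total_umis().astype(float)
    if np.any(totals <= 0):
        raise ValueError(
            "some cells have zero total UMIs; run qc_filter before log_normalize"
        )
    x = sp.csc_matrix(m.counts, dtype=float)
    # scale each column (cell) by scale_factor / total, then log1p in place
    col_scale = scale_factor / totals
    for c in range(x.shape[1]):
        sl = slice(x.indptr[c], x.indptr[c + 1])
        x.data[sl] = np.log1p(x.data[sl] * col_scale[c])
    return NormalizedMatrix(
        values=x.tocsr(),
        gene_meta=m.gene_meta,
        cell_meta=m.cell_meta,
        scale_factor=scale_factor,
        cell_totals=totals,
    )
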