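"""Reading, writing and filtering of UMI count matrices.

The universal container is :class:`CountMatrix`: a dense genes x cells
matrix of non-negative integer molecule counts together with unique gene
and cell identifiers.  Genes are rows and cells are columns everywhere,
matching the orientation of Cell Ranger exports.

Two on-disk dialects are supported: Matrix Market coordinate triplets with
``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` companion files (the
Cell Ranger layout), and dense delimited text with genes in rows and a
header row of cell identifiers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class CountMatrixError(ValueError):
    """Raised when an input fails count-matrix validation."""


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D genes x cells matrix")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)):
                raise CountMatrixError("counts contain NaN or infinite entries")
            if not np.array_equal(self.counts, np.round(self.counts)):
                raise CountMatrixError("counts contain non-integer entries")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise CountMatrixError("counts contain negative entries")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise CountMatrixError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != self.counts.shape[1]:
            raise CountMatrixError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountMatrixError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise CountMatrixError("cell_ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            counts=self.counts[index, :],
            gene_ids=[self.gene_ids[i] for i in index],
            cell_ids=list(self.cell_ids),
        )

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            counts=self.counts[:, index],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), list(self.gene_ids), list(self.cell_ids))


@dataclass
class CellTotals:
    """Per-cell total UMI counts (the default size factors n_i)."""

    totals: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if (self.totals < 0).any():
            raise CountMatrixError("cell totals must be non-negative")


def _read_id_column(path: str) -> list[str]:
    # companion files may be 1-column (id) or multi-column (id, symbol, ...)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_count_matrix(path: str, format: str = "mtx") -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        For ``format="mtx"``: either the ``.mtx`` file itself or the
        directory containing ``matrix.mtx`` plus ``genes.tsv`` (or
        ``features.tsv``) and ``barcodes.tsv``.  For ``format="dense"``:
        a delimited genes-in-rows table whose header names the cells and
        whose first column names the genes.
    format
        ``"mtx"`` or ``"dense"``.
    """
    if format == "mtx":
        if os.path.isdir(path):
            mtx_path = os.path.join(path, "matrix.mtx")
            base = path
        else:
            mtx_path = path
            base = os.path.dirname(path)
        if not os.path.exists(mtx_path):
            raise CountMatrixError(f"matrix file not found: {mtx_path}")
        genes_path = None
        for cand in ("genes.tsv", "features.tsv"):
            p = os.path.join(base, cand)
            if os.path.exists(p):
                genes_path = p
                break
        barcodes_path = os.path.join(base, "barcodes.tsv")
        if genes_path is None or not os.path.exists(barcodes_path):
            raise CountMatrixError(
                "mtx input requires genes.tsv/features.tsv and barcodes.tsv "
                f"companions next to {mtx_path}"
            )
        mat = spio.mmread(mtx_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(barcodes_path)
        return CountMatrix(np.asarray(mat), gene_ids, cell_ids)
    if format == "dense":
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])
    raise CountMatrixError(f"unknown format: {format!r}")


def write_count_matrix(matrix: CountMatrix, path: str, format: str = "mtx") -> None:
    """Write a count matrix; the inverse of :func:`read_count_matrix`."""
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        coo = sparse.coo_matrix(matrix.counts)
        spio.mmwrite(os.path.join(path, "matrix.mtx"), coo, field="integer")
        with open(os.path.join(path, "genes.tsv"), "w") as fh:
            for g in matrix.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
    elif format == "dense":
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.DataFrame(matrix.counts, index=matrix.gene_ids, columns=matrix.cell_ids)
        df.to_csv(path, sep=sep)
    else:
        raise CountMatrixError(f"unknown format: {format!r}")


def filter_genes(matrix: CountMatrix, min_nonzero_cells: int = 5) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_nonzero_cells`` cells.

    The default of 5 is the detection filter applied before model fitting;
    the goodness-of-fit pipeline uses the stricter "more than five cells"
    rule (pass 6).
    """
    if min_nonzero_cells < 0:
        raise CountMatrixError("min_nonzero_cells must be >= 0")
    nonzero = (matrix.counts > 0).sum(axis=1)
    keep = np.flatnonzero(nonzero >= min_nonzero_cells)
    return matrix.subset_genes(keep)


def cell_totals(matrix: CountMatrix) -> CellTotals:
    """Column sums: total UMIs captured per cell."""
    return CellTotals(matrix.counts.sum(axis=0))


def tpm_per_group(matrix: CountMatrix, groups) -> pd.DataFrame:
    """Pooled within-group abundance on the TPM scale.

    For each group, ``tpm(g) = 1e6 * sum_cells counts[g] / sum_cells totals``.
    There is no transcript-length correction: UMI protocols count molecules
    at the 3' end, so pooled count proportions are already abundances.
    Groups with zero total yield NaN columns.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != matrix.n_cells:
        raise CountMatrixError("groups must assign a label to every cell")
    labels = pd.unique(groups)
    out = {}
    for lab in labels:
        cols = matrix.counts[:, groups == lab]
        total = cols.sum()
        if total == 0:
            out[lab] = np.full(matrix.n_genes, np.nan)
        else:
            out[lab] = 1e6 * cols.sum(axis=1) / total
    return pd.DataFrame(out, index=matrix.gene_ids)


def write_table(records: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV with header, 12 significant digits."""
    records.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
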