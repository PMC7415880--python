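"""Readers, writers and preprocessing for single-cell inputs.

Count matrices use the 10x-style Matrix Market triplet (matrix.mtx +
barcodes.tsv + features/genes.tsv, optionally gzipped); protein (ADT)
and label tables are delimited text with a header row and the cell
identifier in the first column. Matrices are cells x genes everywhere
in memory, whatever the on-disk orientation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer expression with identifiers."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if np.any(self.values < 0) or not np.all(np.equal(np.mod(self.values, 1), 0)):
            raise ValueError("expression values must be non-negative integers")
        self.values = self.values.astype(np.int64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"identifier counts ({len(self.cell_ids)} cells, {len(self.gene_ids)} genes) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")

    @property
    def shape(self):
        return self.values.shape

    def subset_cells(self, cell_ids) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return CountMatrix(self.values[idx], list(cell_ids), self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class ProteinTable:
    """Cells x proteins measurements, raw ADT counts or CLR-normalized."""

    values: np.ndarray
    cell_ids: list
    protein_ids: list
    scale: str = "raw"  # "raw" | "clr"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("raw", "clr"):
            raise ValueError("scale must be 'raw' or 'clr'")
        if self.scale == "raw" and np.any(self.values < 0):
            raise ValueError("raw protein counts must be non-negative")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        if self.values.shape != (len(self.cell_ids), len(self.protein_ids)):
            raise ValueError("identifier counts do not match table shape")

    def subset_cells(self, cell_ids) -> "ProteinTable":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return ProteinTable(self.values[idx], list(cell_ids), self.protein_ids, self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.protein_ids)


def _find(directory: Path, stems) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def _read_lines(path: Path) -> list:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_10x_mtx(path) -> CountMatrix:
    """Read a 10x-style Matrix Market triplet directory.

    Accepts both orientations: if the matrix is genes x cells on disk
    (the classic CellRanger layout) it is transposed so that rows are
    cells. Orientation is resolved from the barcode/feature counts.
    """
    directory = Path(path)
    mtx = _find(directory, ["matrix.mtx"])
    barcodes = _find(directory, ["barcodes.tsv"])
    features = _find(directory, ["features.tsv", "genes.tsv"])
    mat = scipy.io.mmread(str(mtx))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    cell_ids = _read_lines(barcodes)
    gene_ids = _read_lines(features)
    if mat.shape == (len(cell_ids), len(gene_ids)):
        pass
    elif mat.shape == (len(gene_ids), len(cell_ids)):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(cell_ids)} barcodes "
            f"x {len(gene_ids)} features nor its transpose"
        )
    return CountMatrix(mat, cell_ids, gene_ids)


def write_10x_mtx(counts: CountMatrix, path) -> None:
    """Write the Matrix Market triplet (genes x cells on disk, 10x convention)."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), scipy.sparse.csr_matrix(counts.values.T))
    (directory / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    (directory / "features.tsv").write_text("\n".join(counts.gene_ids) + "\n")


def read_protein_table(path, scale: str = "raw") -> ProteinTable:
    """Read a delimited cells x proteins table (cell id in first column)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ProteinTable(df.to_numpy(dtype=float), list(df.index), list(df.columns), scale)


def write_protein_table(table: ProteinTable, path) -> None:
    table.to_frame().to_csv(path)


def read_labels(path) -> pd.Series:
    """Read per-cell categorical labels (cell id, label) from delimited text."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return df.iloc[:, 0].astype(str)


def clr_normalize(table: ProteinTable, axis: str = "cell") -> ProteinTable:
    """Centered log-ratio normalization of raw ADT counts.

    Per cell (the compositional convention): ``clr_p = log1p(x_p) -
    mean_q log1p(x_q)``, so each cell's row has zero mean. ``axis="protein"``
    centers each protein across cells instead.
    """
    if table.scale != "raw":
        raise ValueError("clr_normalize expects a raw-scale ProteinTable")
    logged = np.log1p(table.values)
    if axis == "cell":
        clr = logged - logged.mean(axis=1, keepdims=True)
    elif axis == "protein":
        clr = logged - logged.mean(axis=0, keepdims=True)
    else:
        raise ValueError("axis must be 'cell' or 'protein'")
    return ProteinTable(clr, table.cell_ids, table.protein_ids, scale="clr")


def select_variable_genes(counts: CountMatrix, n_top: int) -> CountMatrix:
    """Keep the ``n_top`` genes with the largest variance of log1p counts.

    Original gene order is preserved; ties broken deterministically by
    gene identifier.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > len(counts.gene_ids):
        raise ValueError("n_top exceeds the number of genes")
    variances = np.var(np.log1p(counts.values.astype(float)), axis=0)
    order = sorted(
        range(len(counts.gene_ids)),
        key=lambda j: (-variances[j], counts.gene_ids[j]),
    )
    keep = sorted(order[:n_top])
    return CountMatrix(
        counts.values[:, keep], counts.cell_ids, [counts.gene_ids[j] for j in keep]
    )


def split_train_test(cell_ids, train_fraction: float = 0.9, seed: int = 0):
    """Seeded disjoint, exhaustive train/test partition of cell identifiers.

    ``|train| = round(train_fraction * N)``; at the conventional 90/10
    split, 1000 cells give exactly 900 train and 100 test.
    """
    cell_ids = list(cell_ids)
    n = len(cell_ids)
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [cell_ids[i] for i in sorted(perm[:n_train])]
    test = [cell_ids[i] for i in sorted(perm[n_train:])]
    return train, test
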