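"""Count-matrix containers, 10x-style triplet I/O, QC filters and depth correlation.

The on-disk matrix format is MatrixMarket coordinate integer (``matrix.mtx``)
with ``features.tsv`` / ``barcodes.tsv`` companions, or a dense TSV with gene
ids in the first column and cell ids as the header.  All indices are converted
to 0-based internally.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


@dataclasses.dataclass
class CountMatrix:
    """Sparse nonnegative integer gene-by-cell count matrix.

    Parameters
    ----------
    values
        ``genes x cells`` sparse matrix of raw counts.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids and {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell identifiers")
        if self.values.nnz:
            data = self.values.data
            if not np.issubdtype(data.dtype, np.integer):
                if not np.all(np.isfinite(data)) or np.any(data != np.floor(data)):
                    raise FormatError("count matrix contains non-integer entries")
                self.values = self.values.astype(np.int64)
            if self.values.data.size and self.values.data.min() < 0:
                raise FormatError("count matrix contains negative entries")
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new matrix restricted to the given boolean/integer masks."""
        v = self.values
        g = self.gene_ids
        c = self.cell_ids
        if gene_mask is not None:
            v = v[gene_mask, :]
            g = g[gene_mask]
        if cell_mask is not None:
            v = v[:, cell_mask]
            c = c[cell_mask]
        return CountMatrix(v.tocsr(), g, c)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def __eq__(self, other) -> bool:  # exact structural equality
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.cell_ids, other.cell_ids)
            and (self.values != other.values).nnz == 0
        )


class CellMetadata:
    """Per-cell metadata: sample, sex, replicate and cell-type label.

    Wraps a DataFrame with columns ``cell_id``, ``sample_id``, ``sex``,
    ``replicate``, ``cell_type``.  Each ``sample_id`` must map to exactly one
    sex and ``sex`` must be 'female' or 'male' for every cell.
    """

    REQUIRED = ("cell_id", "sample_id", "sex", "replicate", "cell_type")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {missing}")
        frame = frame.reset_index(drop=True).copy()
        if frame["cell_id"].duplicated().any():
            raise FormatError("duplicate cell_id in metadata")
        bad_sex = set(frame["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex label(s): {sorted(bad_sex)}")
        per_sample = frame.groupby("sample_id")["sex"].nunique()
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index.tolist()
            raise FormatError(f"sample(s) mapped to more than one sex: {bad}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def aligned_to(self, counts: CountMatrix) -> "CellMetadata":
        """Reorder/validate against a CountMatrix; every cell must be covered."""
        idx = self.frame.set_index("cell_id")
        missing = [c for c in counts.cell_ids if c not in idx.index]
        if missing:
            raise FormatError(
                f"{len(missing)} cell id(s) absent from metadata, e.g. {missing[:3]}"
            )
        out = idx.loc[list(counts.cell_ids)].reset_index()
        return CellMetadata(out)

    def subset_cells(self, cell_ids: Iterable[str]) -> "CellMetadata":
        keep = set(cell_ids)
        return CellMetadata(self.frame[self.frame["cell_id"].isin(keep)])

    def write_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "CellMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path: str) -> CountMatrix:
    """Read a count matrix from a triplet directory or a dense TSV file."""
    if os.path.isdir(path):
        return _read_triplet(path)
    return _read_dense_tsv(path)


def _read_triplet(path: str) -> CountMatrix:
    mtx = os.path.join(path, "matrix.mtx")
    feats = os.path.join(path, "features.tsv")
    bcs = os.path.join(path, "barcodes.tsv")
    for f in (mtx, feats, bcs):
        if not os.path.exists(f):
            raise FormatError(f"triplet directory {path!r} is missing {os.path.basename(f)}")
    try:
        mat = mmread(mtx)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    if not np.issubdtype(mat.dtype, np.integer):
        dense_data = mat.tocoo().data
        if np.any(dense_data != np.floor(dense_data)):
            raise FormatError("matrix.mtx contains non-integer entries")
    gene_ids = _read_id_column(feats)
    cell_ids = _read_id_column(bcs)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix declares shape {mat.shape} but features.tsv has "
            f"{len(gene_ids)} rows and barcodes.tsv has {len(cell_ids)} rows"
        )
    return CountMatrix(sp.csr_matrix(mat), gene_ids, cell_ids)


def _read_id_column(path: str) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _read_dense_tsv(path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError(f"non-numeric entries in {path}")
    if np.any(vals != np.floor(vals)):
        raise FormatError(f"non-integer entries in {path}")
    return CountMatrix(
        sp.csr_matrix(vals.astype(np.int64)),
        df.index.astype(str).to_numpy(),
        df.columns.astype(str).to_numpy(),
    )


def write_counts(counts: CountMatrix, path: str) -> None:
    """Write a triplet directory (matrix.mtx + features.tsv + barcodes.tsv)."""
    os.makedirs(path, exist_ok=True)
    mmwrite(
        os.path.join(path, "matrix.mtx"),
        counts.values.tocoo(),
        field="integer",
    )
    # scipy may append .mtx to the target name; normalise
    written = os.path.join(path, "matrix.mtx")
    if not os.path.exists(written) and os.path.exists(written + ".mtx"):
        os.rename(written + ".mtx", written)
    with open(os.path.join(path, "features.tsv"), "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        for c in counts.cell_ids:
            fh.write(f"{c}\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_counts(
    counts: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 100,
    to_fixpoint: bool = False,
) -> CountMatrix:
    """Drop low-support genes, then low-complexity cells.

    Keeps genes detected (count > 0) in at least ``min_cells_per_gene`` cells,
    then — on the reduced matrix — cells with at least ``min_genes_per_cell``
    detected genes.  A single ordered pass by default; ``to_fixpoint=True``
    iterates until no row or column is removed.
    """
    out = counts
    while True:
        before = out.shape
        binar = out.values.copy()
        binar.data = np.ones_like(binar.data)
        cells_per_gene = np.asarray(binar.sum(axis=1)).ravel()
        out = out.subset(gene_mask=cells_per_gene >= min_cells_per_gene)
        binar = out.values.copy()
        binar.data = np.ones_like(binar.data)
        genes_per_cell = np.asarray(binar.sum(axis=0)).ravel()
        out = out.subset(cell_mask=genes_per_cell >= min_genes_per_cell)
        if not to_fixpoint or out.shape == before:
            break
    return out


def filter_counts_per_sample(
    counts: CountMatrix,
    meta: CellMetadata,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 100,
) -> tuple[CountMatrix, CellMetadata]:
    """Apply the gene/cell filters within each sample, then merge.

    A gene survives if it passes the gene filter in at least one sample; a
    cell survives if it passes the cell filter within its own sample (judged
    on that sample's surviving genes).
    """
    meta = meta.aligned_to(counts)
    sample_of = meta.frame["sample_id"].to_numpy()
    kept_gene = np.zeros(counts.n_genes, dtype=bool)
    kept_cells: list[str] = []
    for sample in pd.unique(sample_of):
        cmask = sample_of == sample
        sub = counts.subset(cell_mask=cmask)
        filt = filter_counts(sub, min_cells_per_gene, min_genes_per_cell)
        kept_gene |= np.isin(counts.gene_ids, filt.gene_ids)
        kept_cells.extend(filt.cell_ids)
    keep_cell_mask = np.isin(counts.cell_ids, np.asarray(kept_cells, dtype=object))
    out = counts.subset(gene_mask=kept_gene, cell_mask=keep_cell_mask)
    return out, meta.subset_cells(out.cell_ids)


# ---------------------------------------------------------------------------
# Depth-correlation QC
# ---------------------------------------------------------------------------

def depth_correlation(
    counts: CountMatrix,
    meta: CellMetadata | None = None,
    groupby: str = "cell_type",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Pearson r between per-cell total counts and detected genes, per group.

    Reported for raw counts (``r_raw``) and after per-cell library-size
    scaling to the median total (``r_scaled``); with exact total-count
    scaling the scaled totals are constant, so ``r_scaled`` is typically
    missing — mirroring the removal of the depth effect.  Groups with fewer
    than ``min_cells`` cells, or zero variance in either variable, get NaN.
    """
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    binar = counts.values.copy()
    binar.data = np.ones_like(binar.data)
    ngenes = np.asarray(binar.sum(axis=0)).ravel().astype(float)

    if meta is None:
        groups = np.array(["all"] * counts.n_cells, dtype=object)
    else:
        meta = meta.aligned_to(counts)
        groups = meta.frame[groupby].to_numpy()

    med = np.median(totals) if counts.n_cells else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled_totals = np.where(totals > 0, med, 0.0)  # totals / totals * median

    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        n = int(mask.sum())
        rows.append(
            {
                "group": g,
                "n_cells": n,
                "r_raw": _safe_pearson(totals[mask], ngenes[mask], min_cells),
                "r_scaled": _safe_pearson(scaled_totals[mask], ngenes[mask], min_cells),
            }
        )
    return pd.DataFrame(rows)


def _safe_pearson(x: np.ndarray, y: np.ndarray, min_n: int) -> float:
    if len(x) < min_n or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
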