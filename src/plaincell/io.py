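"""Readers, writers, and the canonical in-memory containers.

Count matrices are held sparse (CSR) as raw, non-negative mRNA counts with
per-cell metadata; densification happens only inside the operations that need
dense arrays.  Gene identifiers are matched by exact, case-sensitive string
equality throughout — any cross-naming (orthology) goes through an explicit
:class:`OrthologMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionMatrix",
    "OrthologMap",
    "load_counts",
    "save_counts",
    "load_ortholog_map",
    "save_table",
    "load_table",
]


@dataclass
class ExpressionMatrix:
    """Sparse cells x genes raw count matrix plus per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative cells x genes matrix (any scipy-sparse or dense array;
        stored as CSR).
    cell_ids, gene_ids
        Unique string identifiers for the rows and columns.
    cell_meta
        Per-cell annotation table indexed like ``cell_ids`` (keys are
        free-form; each analysis names the keys it requires).
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.nnz and self.counts.data.min() < 0:
            r, c = divmod(int(np.argmin(self.counts.toarray())), self.counts.shape[1])
            raise ValueError(
                f"negative count at cell {self.cell_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length does not match count rows")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids length does not match count columns")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                raise ValueError(f"duplicate {name} id: {uniq[counts > 1][0]!r}")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids.astype(str))
        else:
            self.cell_meta = pd.DataFrame(self.cell_meta)
            if len(self.cell_meta) != len(self.cell_ids):
                raise ValueError("cell_meta length does not match cell count")
            self.cell_meta.index = self.cell_ids.astype(str)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def require_meta(self, key: str) -> pd.Series:
        """Return a metadata column, failing fast with a clear message."""
        if key not in self.cell_meta.columns:
            raise KeyError(
                f"metadata key {key!r} not present; available: "
                f"{sorted(self.cell_meta.columns)}"
            )
        return self.cell_meta[key]

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        return ExpressionMatrix(
            self.counts[idx],
            self.cell_ids[idx],
            self.gene_ids,
            self.cell_meta.iloc[np.arange(self.n_cells)[idx] if idx.dtype == bool else idx],
        )

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.counts[:, idx], self.cell_ids, self.gene_ids[idx], self.cell_meta
        )


@dataclass
class OrthologMap:
    """Strictly one-to-one gene correspondence between two species."""

    pairs: list[tuple[str, str]]
    source_species: str = "source"
    basis_species: str = "basis"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        src = [p[0] for p in self.pairs]
        dst = [p[1] for p in self.pairs]
        if len(set(src)) != len(src) or len(set(dst)) != len(dst):
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def inverse(self) -> "OrthologMap":
        return OrthologMap(
            [(b, a) for a, b in self.pairs], self.basis_species, self.source_species
        )


def load_counts(path, format_hint: str | None = None) -> ExpressionMatrix:
    """Load a count matrix from MTX-triplet, dense CSV, or h5ad.

    ``format_hint`` is one of ``"mtx"``, ``"csv"``, ``"h5ad"``; when omitted it
    is taken from the file suffix.  MTX follows the 10x triplet convention:
    ``barcodes.tsv`` and ``features.tsv`` adjacent to the matrix file, cells in
    columns of the MatrixMarket file.  CSV is dense with gene IDs in the
    header row and cell IDs in the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format_hint or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        mat = sp.csr_matrix(mmread(path).T)
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
        for companion in (barcodes, features):
            if not companion.exists():
                raise FileNotFoundError(f"missing MTX companion file {companion}")
        cells = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).to_numpy()
        genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).to_numpy()
        return ExpressionMatrix(mat, cells, genes)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric entries in CSV count matrix")
        neg = np.argwhere(arr < 0)
        if len(neg):
            r, c = neg[0]
            raise ValueError(
                f"negative count at cell {df.index[r]!r}, gene {df.columns[c]!r}"
            )
        return ExpressionMatrix(
            sp.csr_matrix(arr), df.index.astype(str).to_numpy(), df.columns.astype(str).to_numpy()
        )
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        return ExpressionMatrix(
            sp.csr_matrix(adata.X),
            adata.obs_names.to_numpy(),
            adata.var_names.to_numpy(),
            adata.obs.copy(),
        )
    raise ValueError(f"unknown format {fmt!r}; expected mtx, csv, or h5ad")


def save_counts(matrix: ExpressionMatrix, path, format_hint: str | None = None) -> None:
    """Write a count matrix in the format implied by the path suffix."""
    path = Path(path)
    fmt = format_hint or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path), sp.coo_matrix(matrix.counts.T))
        pd.Series(matrix.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(matrix.gene_ids).to_csv(
            path.parent / "features.tsv", sep="\t", header=False, index=False
        )
    elif fmt == "csv":
        pd.DataFrame(
            matrix.counts.toarray(), index=matrix.cell_ids, columns=matrix.gene_ids
        ).to_csv(path)
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(matrix.counts),
            obs=matrix.cell_meta.copy(),
            var=pd.DataFrame(index=matrix.gene_ids.astype(str)),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_ortholog_map(
    path, source_species: str = "source", basis_species: str = "basis"
) -> OrthologMap:
    """Load a two-column TSV (source_gene, basis_gene) as a one-to-one map.

    Rows participating in many-to-many or duplicated relations are dropped
    entirely; the count of dropped rows is kept on the returned map.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog TSV needs at least two columns")
    src, dst = df.iloc[:, 0], df.iloc[:, 1]
    src_dup = src.duplicated(keep=False)
    dst_dup = dst.duplicated(keep=False)
    keep = ~(src_dup | dst_dup)
    n_dropped = int((~keep).sum())
    pairs = list(zip(src[keep], dst[keep]))
    if not pairs:
        raise ValueError("no one-to-one orthologs")
    return OrthologMap(pairs, source_species, basis_species, n_dropped=n_dropped)


def save_ortholog_map(omap: OrthologMap, path) -> None:
    pd.DataFrame(omap.pairs, columns=["source_gene", "basis_gene"]).to_csv(
        path, sep="\t", index=False
    )


def save_table(rows: pd.DataFrame, path) -> None:
    """Write a rectangular, non-empty result table as TSV with header."""
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
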