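"""Per-cell rank-based inverse-normal transform.

Each cell is normalized to itself: raw counts are replaced by the z-score of
their within-cell rank percentile,

    z_g = Phi^{-1}((rank_g - 0.5) / n),

with fractional (average) ranks for ties and Phi the standard normal CDF.
A gene at the within-cell median maps to z = 0; one at the 84th percentile to
z ~= 1.  Because the transform depends only on the rank ordering inside a
cell, it is invariant to library size and any cell-wise monotone distortion,
which is what removes multiplicative batch effects: every cell is normalized
independently of all others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix

__all__ = ["NormalizedMatrix", "rank_zscore", "rank_zscore_vector"]


@dataclass
class NormalizedMatrix:
    """Dense cells x genes matrix of within-cell rank z-scores."""

    z: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.z.shape[0]

    @property
    def n_genes(self) -> int:
        return self.z.shape[1]

    def gene_column(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if not len(idx):
            raise KeyError(f"gene {gene_id!r} not present")
        return self.z[:, idx[0]]


def rank_zscore_vector(counts: np.ndarray) -> np.ndarray:
    """Rank z-score of a single expression vector (one cell or pseudo-bulk)."""
    counts = np.asarray(counts, dtype=float).ravel()
    n = counts.size
    if n < 2:
        raise ValueError("rank z-score needs at least 2 genes per cell")
    ranks = rankdata(counts, method="average")
    return norm.ppf((ranks - 0.5) / n)


def rank_zscore(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Apply the within-cell rank z-score transform to every cell.

    All genes participate in the ranking, including never-detected ones: in a
    typical cell the zero counts form one large tie block that maps to a
    single shared negative z value.
    """
    if matrix.n_genes < 2:
        raise ValueError("rank z-score needs at least 2 genes per cell")
    dense = matrix.counts.toarray() if sp.issparse(matrix.counts) else np.asarray(matrix.counts)
    ranks = rankdata(dense, method="average", axis=1)
    z = norm.ppf((ranks - 0.5) / matrix.n_genes)
    return NormalizedMatrix(z, matrix.cell_ids, matrix.gene_ids)
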