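"""Parameter-free cell-type annotation by projection onto a pseudo-bulk basis.

A reference basis is a genes x types matrix whose columns are normalized
pseudo-bulk profiles, one per source cell type.  Because the number of genes
far exceeds the number of types, the types span a low-dimensional linear
subspace of gene space; a target cell (its rank z-score row) is classified by
its non-orthogonal linear projection onto that subspace — the least-squares
coordinates a = (B'B)^{-1} B' x — and labeled with the type of the largest
coordinate.  No weights are trained anywhere.

Cross-species transfer first restricts both sides to one-to-one orthologs and
renames target genes into the basis species' namespace, defining a shared
coordinate system in gene space.  The restriction is inherently lossy: the
retained-gene count is reported alongside the harmonized matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, OrthologMap
from .normalization import NormalizedMatrix, rank_zscore, rank_zscore_vector

__all__ = [
    "ReferenceBasis",
    "ProjectionScores",
    "build_reference",
    "project_cells",
    "harmonize_orthologs",
    "cross_species_annotate",
]

# relative singular-value floor below which basis columns count as dependent
_COND_TOL = 1e-10


@dataclass
class ReferenceBasis:
    """Genes x types matrix of normalized pseudo-bulk profiles."""

    B: np.ndarray
    type_labels: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.type_labels = np.asarray(self.type_labels, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.B.shape[1] >= self.B.shape[0]:
            raise ValueError("basis needs more genes than cell types")
        s = np.linalg.svd(self.B, compute_uv=False)
        if s[-1] <= _COND_TOL * s[0]:
            # name the most collinear column pair for the error message
            C = np.corrcoef(self.B.T)
            np.fill_diagonal(C, 0.0)
            i, j = divmod(int(np.abs(C).argmax()), C.shape[1])
            raise ValueError(
                "basis columns are linearly dependent (near-collinear pair: "
                f"{self.type_labels[i]!r}, {self.type_labels[j]!r})"
            )


@dataclass
class ProjectionScores:
    """Per-cell projection coefficients onto the basis, with argmax labels."""

    A: np.ndarray
    type_labels: np.ndarray
    cell_ids: np.ndarray
    predicted: np.ndarray = field(init=False)
    margin: np.ndarray = field(init=False)
    tie_flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        order = np.argsort(self.type_labels.astype(str), kind="stable")
        # lexicographically smallest label wins ties: scan labels in sorted
        # order and keep the first achieving the row maximum
        top = A.max(axis=1)
        pred_idx = np.empty(A.shape[0], dtype=int)
        ties = np.zeros(A.shape[0], dtype=bool)
        for r in range(A.shape[0]):
            hits = order[A[r, order] == top[r]]
            pred_idx[r] = hits[0]
            ties[r] = len(hits) > 1
        runner_up = np.partition(A, -2, axis=1)[:, -2] if A.shape[1] > 1 else top
        self.predicted = self.type_labels[pred_idx]
        self.margin = top - runner_up
        self.tie_flags = ties


def build_reference(
    matrix: ExpressionMatrix, label_key: str, method: str = "sum"
) -> ReferenceBasis:
    """Build a reference basis of normalized pseudo-bulk profiles.

    ``method="sum"`` (default) sums raw counts across each label's cells and
    rank-z-normalizes the summed pseudo-bulk vector; ``method="mean_z"``
    instead averages the per-cell rank z-scores of the label's cells.
    """
    labels = matrix.require_meta(label_key).to_numpy()
    uniq = np.unique(labels.astype(str))
    cols, kept = [], []
    if method == "mean_z":
        z_all = rank_zscore(matrix).z
    for lab in uniq:
        idx = np.flatnonzero(labels.astype(str) == lab)
        if method == "sum":
            bulk = np.asarray(matrix.counts[idx].sum(axis=0)).ravel()
            cols.append(rank_zscore_vector(bulk))
        elif method == "mean_z":
            cols.append(z_all[idx].mean(axis=0))
        else:
            raise ValueError(f"unknown pseudo-bulk method {method!r}")
        kept.append(lab)
    return ReferenceBasis(np.column_stack(cols), np.array(kept, dtype=object), matrix.gene_ids)


def project_cells(basis: ReferenceBasis, z: NormalizedMatrix) -> ProjectionScores:
    """Least-squares coordinates of every cell in the basis's column span."""
    if len(basis.gene_ids) != len(z.gene_ids) or not np.array_equal(
        basis.gene_ids.astype(str), z.gene_ids.astype(str)
    ):
        mism = _first_gene_mismatch(basis.gene_ids, z.gene_ids)
        raise ValueError(f"gene sets not aligned with basis; first disagreement: {mism}")
    A, *_ = np.linalg.lstsq(basis.B, z.z.T, rcond=None)
    return ProjectionScores(A.T, basis.type_labels, z.cell_ids)


def _first_gene_mismatch(a: np.ndarray, b: np.ndarray) -> str:
    a, b = a.astype(str), b.astype(str)
    if len(a) != len(b):
        return f"lengths differ ({len(a)} vs {len(b)})"
    pos = int(np.flatnonzero(a != b)[0])
    return f"position {pos}: {a[pos]!r} vs {b[pos]!r}"


def harmonize_orthologs(
    target: ExpressionMatrix, omap: OrthologMap, basis_genes
) -> tuple[ExpressionMatrix, int]:
    """Rename target genes via the ortholog map and align to basis gene order.

    Returns the restricted matrix (genes renamed to basis-species IDs, in
    basis order) and the retained-gene count.  Genes without a one-to-one
    ortholog in the basis are dropped.
    """
    mapping = omap.as_dict()
    basis_genes = np.asarray(basis_genes, dtype=object)
    basis_set = {g: i for i, g in enumerate(basis_genes.astype(str))}
    src_idx, dst_order = [], []
    for j, g in enumerate(target.gene_ids.astype(str)):
        mapped = mapping.get(g)
        if mapped is not None and mapped in basis_set:
            src_idx.append(j)
            dst_order.append(basis_set[mapped])
    if not src_idx:
        raise ValueError("no target genes map into the basis gene set")
    order = np.argsort(dst_order)
    src_idx = np.asarray(src_idx)[order]
    new_genes = basis_genes[np.asarray(dst_order)[order]]
    out = ExpressionMatrix(
        target.counts[:, src_idx], target.cell_ids, new_genes, target.cell_meta
    )
    return out, len(src_idx)


@dataclass
class EvaluationSummary:
    macro_f1: float
    per_class_f1: dict
    n_retained_genes: int


def cross_species_annotate(
    source: ExpressionMatrix,
    label_key: str,
    target: ExpressionMatrix,
    omap: OrthologMap | None = None,
    truth_key: str | None = None,
    method: str = "sum",
):
    """Annotate target cells with source cell types by basis projection.

    When an ortholog map is given, both source and target are restricted to
    the shared one-to-one orthologs (the target renamed into the source
    namespace) before the basis is built.  Returns ``ProjectionScores`` and,
    if ``truth_key`` names a target metadata column, an evaluation summary
    with the macro F1 against that truth.
    """
    n_retained = len(source.gene_ids)
    if omap is not None:
        target, n_retained = harmonize_orthologs(target, omap, source.gene_ids)
        shared = set(target.gene_ids.astype(str))
        keep = np.array([g in shared for g in source.gene_ids.astype(str)])
        source = source.subset_genes(np.flatnonzero(keep))
    elif not np.array_equal(source.gene_ids.astype(str), target.gene_ids.astype(str)):
        raise ValueError("species gene sets differ; an ortholog map is required")
    basis = build_reference(source, label_key, method=method)
    scores = project_cells(basis, rank_zscore(target))
    if truth_key is None:
        return scores, None
    from .classify import macro_f1

    report = macro_f1(target.require_meta(truth_key).to_numpy(), scores.predicted)
    return scores, EvaluationSummary(report.macro_f1, report.per_class_f1, n_retained)
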