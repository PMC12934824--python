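"""Cosine similarity of group-level expression profiles.

Group profiles (per cell type or per species) are normalized pseudo-bulk
vectors built exactly like reference-basis columns.  Their pairwise cosine
similarities expose global biological structure: developmental stages that
are adjacent in a lineage are more alike than distant ones, and species-level
profiles grow less similar with evolutionary divergence — quantified here as
the Spearman rank correlation between an anchor species' similarities and
user-supplied divergence times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import ExpressionMatrix
from .normalization import rank_zscore_vector

__all__ = [
    "SimilarityReport",
    "group_profiles",
    "cosine_matrix",
    "similarity_vs_distance",
]


@dataclass
class SimilarityReport:
    labels: np.ndarray
    S: np.ndarray
    spearman_r: float | None = None
    distance_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)


def group_profiles(matrix: ExpressionMatrix, group_key: str) -> dict[str, np.ndarray]:
    """Per-group normalized pseudo-bulk vectors (sum counts, then rank z).

    Works for cell-type and species groupings alike; for cross-species
    comparisons the caller restricts the matrix to shared orthologs and
    shared cell types first.  Unlike a reference basis, identical group
    profiles are legitimate here (their cosine similarity is simply 1).
    """
    labels = matrix.require_meta(group_key).astype(str).to_numpy()
    out = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        bulk = np.asarray(matrix.counts[idx].sum(axis=0)).ravel()
        out[str(lab)] = rank_zscore_vector(bulk)
    return out


def cosine_matrix(vectors: dict[str, np.ndarray]) -> SimilarityReport:
    """Pairwise cosine similarity matrix of labeled vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    labels = np.array(list(vectors), dtype=object)
    V = np.column_stack([np.asarray(vectors[str(l)], dtype=float) for l in labels])
    norms = np.linalg.norm(V, axis=0)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"zero-norm vector: {labels[zero[0]]!r}")
    U = V / norms
    S = np.clip(U.T @ U, -1.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityReport(labels, S)


def similarity_vs_distance(
    report: SimilarityReport, anchor: str, distances
) -> float:
    """Spearman correlation of anchor similarities vs divergence times.

    ``distances`` is an iterable of (label, time) pairs or a mapping; every
    non-anchor label in the report must have a distance entry.  Ties get
    average-rank correction; an all-tied similarity vector is rejected rather
    than silently reported as zero.
    """
    dist = dict(distances.items() if hasattr(distances, "items") else distances)
    labels = [str(l) for l in report.labels]
    if anchor not in labels:
        raise KeyError(f"anchor {anchor!r} not among labels")
    others = [l for l in labels if l != anchor]
    missing = [l for l in others if l not in dist]
    if missing:
        raise KeyError(f"no divergence time for {missing[0]!r}")
    if len(others) < 3:
        raise ValueError("need at least 3 comparison points for a rank correlation")
    ai = labels.index(anchor)
    sims = np.array([report.S[ai, labels.index(l)] for l in others], dtype=float)
    times = np.array([float(dist[l]) for l in others])
    if np.ptp(sims) < 1e-12 or np.ptp(times) < 1e-12:
        raise ValueError("rank correlation undefined: one input is constant")
    r = spearmanr(sims, times).statistic
    report.spearman_r = float(r)
    report.distance_table = pd.DataFrame({"label": others, "divergence_time": times})
    return float(r)
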