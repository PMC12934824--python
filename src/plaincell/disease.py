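"""Disease-state prediction with cluster-local classifiers.

Disease signatures are often locally distinguishable but not globally
separable: healthy and infected cells of the same type are highly
correlated, the direction separating them can differ between transcriptional
neighborhoods, and class balance varies wildly across neighborhoods.  The
pipeline therefore denoises (rank z-score, ANOVA gene selection,
standardization, PCA), partitions PC space into biologically coherent
regions with Leiden community detection on a k-nearest-neighbor graph —
computed without any knowledge of health status — and fits a separate binary
logistic classifier inside each cluster.  Clusters containing a single class
(for instance regions overwhelmingly composed of healthy cells) get a
constant predictor.

Held-out cells are routed through the train-fitted front end, assigned to
the nearest train-cluster centroid in PC space, and scored by that cluster's
predictor.  With a single cluster the procedure reduces exactly to one
global classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .classify import (
    EvaluationReport,
    anova_select,
    macro_f1,
    standardize_apply,
    standardize_fit,
)
from .io import ExpressionMatrix
from .normalization import NormalizedMatrix, rank_zscore

__all__ = ["LocalModel", "cluster_cells", "fit_local", "predict_disease"]

logger = logging.getLogger(__name__)


def cluster_cells(
    pc_scores: np.ndarray,
    target_clusters: int = 15,
    k_neighbors: int = 15,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Leiden clustering of PC space, tuned toward a target cluster count.

    Builds a symmetric ("union") k-nearest-neighbor graph with Euclidean
    edges, then binary-searches the Leiden resolution until the community
    count lands within +/-20% of ``target_clusters`` or 20 iterations elapse.
    Returns the labels and the resolution used.
    """
    X = np.asarray(pc_scores, dtype=float)
    n = X.shape[0]
    if n < target_clusters:
        raise ValueError("fewer cells than target clusters")
    if np.ptp(X, axis=0).max() == 0:
        warnings.warn("all points identical; returning a single cluster")
        return np.zeros(n, dtype=int), 0.0
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges))
    if len(g.connected_components()) > target_clusters:
        warnings.warn("k-NN graph has more components than target clusters")

    def run(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        return np.asarray(part.membership)

    lo, hi, res = 1e-4, 50.0, 1.0
    labels = run(res)
    band = (0.8 * target_clusters, 1.2 * target_clusters)
    for _ in range(20):
        n_found = len(np.unique(labels))
        if band[0] <= n_found <= band[1]:
            break
        if n_found < band[0]:
            lo = res
        else:
            hi = res
        res = (lo + hi) / 2.0
        labels = run(res)
    n_found = len(np.unique(labels))
    if not band[0] <= n_found <= band[1]:
        warnings.warn(
            f"resolution search ended with {n_found} clusters, outside the "
            f"target band around {target_clusters}"
        )
    logger.info(
        "cluster_cells: %d clusters at resolution %.4g (target %d)",
        len(np.unique(labels)), res, target_clusters,
    )
    return labels, res


@dataclass
class LocalModel:
    """Front-end transforms plus per-cluster predictors."""

    selected_genes: np.ndarray
    gene_ids: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    pca_components: np.ndarray
    centroids: np.ndarray            # n_clusters x n_pc
    cluster_ids: np.ndarray
    local_classifiers: dict          # cluster id -> LogisticRegression or None
    majority_class: dict             # cluster id -> constant fallback label
    resolution: float
    n_clusters: int

    def transform(self, z: NormalizedMatrix) -> np.ndarray:
        if not np.array_equal(z.gene_ids.astype(str), self.gene_ids.astype(str)):
            raise ValueError("gene universe incompatible with fitted model")
        X = standardize_apply(z.z[:, self.selected_genes], self.means, self.sds)
        return X @ self.pca_components

    def assign_clusters(self, scores: np.ndarray) -> np.ndarray:
        """Nearest-centroid cluster assignment; ties go to the lower index."""
        d = cdist(scores, self.centroids)
        return self.cluster_ids[np.argmin(d, axis=1)]


def fit_local(
    matrix: ExpressionMatrix,
    disease_key: str,
    n_genes: int = 20000,
    n_pc: int = 220,
    target_clusters: int = 15,
    k_neighbors: int = 15,
    C: float = 1.0,
    seed: int = 0,
) -> LocalModel:
    """Fit the denoising front end, cluster PC space, fit local classifiers.

    ANOVA gene selection groups cells by disease state (the only label
    available before clustering); clustering itself never sees the disease
    labels — they enter only when each cluster's classifier is fit.
    """
    y = matrix.require_meta(disease_key).astype(str).to_numpy()
    states = np.unique(y)
    if len(states) > 2:
        raise ValueError(f"disease key must be binary; found {list(states)}")
    z = rank_zscore(matrix)
    if len(states) == 2:
        sel = anova_select(z, y, n_genes=n_genes)
    else:
        sel = np.arange(min(n_genes, z.n_genes))
    X = z.z[:, sel]
    means, sds = standardize_fit(X)
    Xs = standardize_apply(X, means, sds)
    n_pc = min(n_pc, Xs.shape[0] - 1, Xs.shape[1])
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_pc, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(Xs)
    if target_clusters == 1:
        labels = np.zeros(len(y), dtype=int)
        res = 0.0
    else:
        labels, res = cluster_cells(
            scores, target_clusters=target_clusters, k_neighbors=k_neighbors, seed=seed
        )
    cluster_ids = np.unique(labels)
    centroids = np.vstack([scores[labels == c].mean(axis=0) for c in cluster_ids])
    classifiers, majority = {}, {}
    for c in cluster_ids:
        mask = labels == c
        yc = y[mask]
        vals, counts = np.unique(yc, return_counts=True)
        majority[int(c)] = vals[counts.argmax()]
        if len(vals) == 2:
            clf = LogisticRegression(C=C, max_iter=5000, random_state=seed)
            clf.fit(scores[mask], yc)
            classifiers[int(c)] = clf
        else:
            classifiers[int(c)] = None
    return LocalModel(
        selected_genes=sel,
        gene_ids=np.asarray(matrix.gene_ids),
        means=means,
        sds=sds,
        pca_components=pca.components_.T.copy(),
        centroids=centroids,
        cluster_ids=cluster_ids,
        local_classifiers=classifiers,
        majority_class=majority,
        resolution=res,
        n_clusters=len(cluster_ids),
    )


def predict_disease(
    model: LocalModel, matrix: ExpressionMatrix, truth_key: str | None = None
) -> tuple[np.ndarray, EvaluationReport | None]:
    """Route cells to their nearest cluster and apply its local predictor."""
    scores = model.transform(rank_zscore(matrix))
    clusters = model.assign_clusters(scores)
    pred = np.empty(len(clusters), dtype=object)
    for c in np.unique(clusters):
        mask = clusters == c
        clf = model.local_classifiers[int(c)]
        if clf is None:
            pred[mask] = model.majority_class[int(c)]
        else:
            pred[mask] = clf.predict(scores[mask])
    report = None
    if truth_key is not None:
        report = macro_f1(matrix.require_meta(truth_key).to_numpy(), pred)
    return pred.astype(str), report
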