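"""Geodesic-vs-Euclidean linearity diagnostic.

If a dataset lies on (a convex region of) a linear subspace, shortest-path
distances along a k-nearest-neighbor graph approximate straight-line
Euclidean distances and the two are almost perfectly correlated; on a curved
manifold such as a swiss roll, geodesics must wind along the surface and the
correlation drops.  Sweeping the neighbor count k and reading the Pearson
correlation between the two distance sets is therefore a practical test of
whether data that looks high-dimensional is in fact near-linear.

The k-NN graph is the symmetric ("union") graph — an edge exists if either
endpoint lists the other — which stays connected at smaller k than the
mutual variant.  Correlations are computed over connected pairs only, and
the component count is always reported so disconnection cannot silently
inflate the correlation.  The Isomap embedding is classical MDS on the
squared geodesic matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "GeodesicReport",
    "geodesic_distances",
    "linearity_correlation",
    "isomap_embed",
    "pca_scores",
]


@dataclass
class GeodesicReport:
    k: int
    n_points: int
    pearson_r: float
    n_components: int
    n_pairs: int
    embedding: np.ndarray | None = None


def _knn_graph(points: np.ndarray, k: int) -> csr_matrix:
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    G = kneighbors_graph(points, n_neighbors=k, mode="distance")
    return G.maximum(G.T)  # union graph: edge if either endpoint lists the other


def geodesic_distances(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances on the symmetric k-NN graph.

    Edge weights are Euclidean; unreachable pairs are infinite.  Returns the
    geodesic matrix and the connected-component label of each point.
    """
    points = np.asarray(points, dtype=float)
    G = _knn_graph(points, k)
    D = shortest_path(G, method="D", directed=False)
    _, labels = connected_components(G, directed=False)
    return D, labels


def linearity_correlation(points: np.ndarray, k_values) -> list[GeodesicReport]:
    """Pearson r between geodesic and Euclidean distances for each k.

    Only finite (connected) upper-triangle pairs enter the correlation; a k
    whose graph leaves fewer than 3 connected pairs is reported with r = NaN.
    """
    points = np.asarray(points, dtype=float)
    eucl = squareform(pdist(points))
    iu = np.triu_indices(points.shape[0], k=1)
    reports = []
    for k in k_values:
        D, labels = geodesic_distances(points, k)
        geo = D[iu]
        finite = np.isfinite(geo)
        if finite.sum() < 3:
            r = np.nan
        else:
            r = float(pearsonr(eucl[iu][finite], geo[finite]).statistic)
        reports.append(
            GeodesicReport(
                k=int(k),
                n_points=points.shape[0],
                pearson_r=r,
                n_components=len(np.unique(labels)),
                n_pairs=int(finite.sum()),
            )
        )
    return reports


def isomap_embed(points: np.ndarray, k: int, out_dim: int = 2) -> np.ndarray:
    """Classical-MDS embedding of the geodesic distance matrix.

    If the k-NN graph is disconnected the largest component is embedded and
    a warning is issued; rows for points outside it are NaN.  Coordinates
    are the top ``out_dim`` eigenvectors of the double-centered squared
    geodesic matrix, scaled by the square roots of their eigenvalues.
    """
    points = np.asarray(points, dtype=float)
    D, labels = geodesic_distances(points, k)
    uniq, counts = np.unique(labels, return_counts=True)
    keep = np.arange(points.shape[0])
    if len(uniq) > 1:
        warnings.warn(
            f"k-NN graph has {len(uniq)} components; embedding the largest"
        )
        keep = np.flatnonzero(labels == uniq[counts.argmax()])
        D = D[np.ix_(keep, keep)]
    n = len(keep)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval[:out_dim] <= 1e-12 * max(1.0, abs(eigval[0]))).any():
        raise ValueError(
            f"fewer than {out_dim} positive eigenvalues; points may be degenerate"
        )
    coords = eigvec[:, :out_dim] * np.sqrt(eigval[:out_dim])
    out = np.full((points.shape[0], out_dim), np.nan)
    out[keep] = coords
    return out


def pca_scores(z_matrix: np.ndarray, n_components: int = 50) -> np.ndarray:
    """Leading PCA scores of a (normalized) expression matrix.

    Raw gene space is too high-dimensional for meaningful k-NN searches at
    modest cell counts, so expression inputs to the linearity diagnostic are
    first reduced to their leading principal components.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(z_matrix, dtype=float)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_components, svd_solver="auto", random_state=0).fit_transform(X)
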