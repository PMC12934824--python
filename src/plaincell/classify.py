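"""Denoised tissue-level cell-type classification.

Pipeline: drop cell types below a minimum size, rank z-score each cell,
select the genes that vary most across cell types by one-way ANOVA, per-gene
standardize with training statistics, project onto the leading principal
components, and fit a multinomial logistic classifier on the scores.  All
statistics (gene selection, standardization means/sds, PCA loadings) are
estimated from training cells only and applied unchanged to held-out cells,
so no information leaks from the test set into the fitted model.

Defaults follow the atlas-scale protocol: at least 100 cells per type,
20000 ANOVA-selected genes, 220 principal components, an 80-20 stratified
split realized as five-fold cross-validation, macro F1 as the headline
metric (unweighted over classes, so rare types count as much as common
ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix
from .normalization import NormalizedMatrix, rank_zscore

__all__ = [
    "DenoiseModel",
    "EvaluationReport",
    "filter_rare_types",
    "anova_select",
    "anova_f_statistic",
    "fit_denoise_model",
    "predict_types",
    "macro_f1",
    "crossvalidate",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    macro_f1: float
    per_class_f1: dict
    confusion: np.ndarray
    class_labels: np.ndarray
    n_folds: int = 1
    fold_scores: list = field(default_factory=list)


@dataclass
class DenoiseModel:
    """Frozen train-side state: gene selection, scaling, PCA, classifier."""

    selected_genes: np.ndarray
    gene_ids: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    pca_components: np.ndarray  # selected_genes x n_pc, columns orthonormal
    classifier: LogisticRegression
    class_labels: np.ndarray

    def transform(self, z: NormalizedMatrix) -> np.ndarray:
        """Apply the train-fitted front end (select, standardize, PCA)."""
        if not np.array_equal(z.gene_ids.astype(str), self.gene_ids.astype(str)):
            z = _align_genes(z, self.gene_ids)
        X = z.z[:, self.selected_genes]
        X = standardize_apply(X, self.means, self.sds)
        return X @ self.pca_components


def _align_genes(z: NormalizedMatrix, gene_ids: np.ndarray) -> NormalizedMatrix:
    pos = {g: i for i, g in enumerate(z.gene_ids.astype(str))}
    try:
        idx = np.array([pos[g] for g in gene_ids.astype(str)])
    except KeyError as e:
        raise ValueError(f"gene {e.args[0]!r} missing from input") from None
    return NormalizedMatrix(z.z[:, idx], z.cell_ids, np.asarray(gene_ids))


def filter_rare_types(
    matrix: ExpressionMatrix, label_key: str, min_cells: int = 100
) -> ExpressionMatrix:
    """Remove cells whose label occurs fewer than ``min_cells`` times."""
    labels = matrix.require_meta(label_key).astype(str).to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    keep_labels = set(uniq[counts >= min_cells])
    if not keep_labels:
        raise ValueError(f"no cell type has at least {min_cells} cells")
    mask = np.array([l in keep_labels for l in labels])
    surviving = {l: int(c) for l, c in zip(uniq, counts) if l in keep_labels}
    logger.info("filter_rare_types kept %s", surviving)
    return matrix.subset_cells(mask)


def anova_f_statistic(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F statistic per column (gene).

    F = [sum_g n_g (mean_g - mean)^2 / (G-1)] / [sum_g SS_within_g / (N-G)].
    Columns with zero within-group variance and positive between-group
    variance get +inf; columns constant everywhere get 0 (and all-degenerate
    columns sort last via a NaN->0 convention handled by the caller).
    """
    labels = np.asarray(labels).astype(str)
    uniq = np.unique(labels)
    N, G = X.shape[0], len(uniq)
    if G < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if N <= G:
        raise ValueError("ANOVA degenerate: no within-group degrees of freedom")
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for g in uniq:
        sub = X[labels == g]
        m = sub.mean(axis=0)
        ss_between += sub.shape[0] * (m - grand) ** 2
        ss_within += ((sub - m) ** 2).sum(axis=0)
    msb = ss_between / (G - 1)
    msw = ss_within / (N - G)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F[(msw == 0) & (msb > 0)] = np.inf
    F[(msw == 0) & (msb == 0)] = 0.0
    return F


def anova_select(z: NormalizedMatrix, labels, n_genes: int = 20000) -> np.ndarray:
    """Indices of the ``n_genes`` genes with the largest one-way F.

    Degenerate genes (no variance anywhere) rank last; ties at the selection
    boundary keep the lower gene index for determinism.
    """
    F = anova_f_statistic(z.z, np.asarray(labels))
    if n_genes >= len(F):
        return np.arange(len(F))
    # stable sort on (-F, index): equal F keeps lower index first
    order = np.lexsort((np.arange(len(F)), -F))
    return np.sort(order[:n_genes])


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    return means, sds


def standardize_apply(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    # zero-variance features become exactly 0, keeping index bookkeeping stable
    safe = np.where(sds == 0, 1.0, sds)
    out = (X - means) / safe
    out[:, sds == 0] = 0.0
    return out


def fit_denoise_model(
    z: NormalizedMatrix,
    labels,
    n_genes: int = 20000,
    n_pc: int = 220,
    C: float = 1.0,
    seed: int = 0,
) -> DenoiseModel:
    """Fit gene selection, scaling, PCA and the multinomial classifier.

    ``n_pc`` is clipped to the PCA rank bound min(n_cells - 1, n selected
    genes) with a logged warning.
    """
    labels = np.asarray(labels).astype(str)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    sel = anova_select(z, labels, n_genes=n_genes)
    X = z.z[:, sel]
    means, sds = standardize_fit(X)
    Xs = standardize_apply(X, means, sds)
    rank_bound = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_pc > rank_bound:
        logger.warning("n_pc=%d exceeds rank bound %d; clipping", n_pc, rank_bound)
        n_pc = rank_bound
    pca = PCA(n_components=n_pc, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(Xs)
    clf = LogisticRegression(C=C, max_iter=5000, random_state=seed)
    clf.fit(scores, labels)
    return DenoiseModel(
        selected_genes=sel,
        gene_ids=np.asarray(z.gene_ids),
        means=means,
        sds=sds,
        pca_components=pca.components_.T.copy(),
        classifier=clf,
        class_labels=clf.classes_,
    )


def predict_types(model: DenoiseModel, z: NormalizedMatrix) -> np.ndarray:
    """Predict one label per cell using the train-fitted transforms."""
    return model.classifier.predict(model.transform(z))


def macro_f1(truth, pred) -> EvaluationReport:
    """Macro F1 over the classes present in ``truth``.

    Per class: F1 = 2 * precision * recall / (precision + recall), defined as
    0 when precision + recall = 0; the macro score is the unweighted mean over
    truth classes, so predicted-only classes add confusion columns but do not
    enter the mean.
    """
    truth = np.asarray(truth).astype(str)
    pred = np.asarray(pred).astype(str)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    if not len(truth):
        raise ValueError("empty evaluation")
    truth_classes = np.unique(truth)
    all_classes = np.unique(np.concatenate([truth, pred]))
    pos = {c: i for i, c in enumerate(all_classes)}
    conf = np.zeros((len(all_classes), len(all_classes)), dtype=int)
    for t, p in zip(truth, pred):
        conf[pos[t], pos[p]] += 1
    per_class = {}
    for c in truth_classes:
        i = pos[c]
        tp = conf[i, i]
        prec = tp / conf[:, i].sum() if conf[:, i].sum() else 0.0
        rec = tp / conf[i, :].sum() if conf[i, :].sum() else 0.0
        per_class[c] = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    macro = float(np.mean(list(per_class.values())))
    return EvaluationReport(macro, per_class, conf, all_classes)


def crossvalidate(
    matrix: ExpressionMatrix,
    label_key: str,
    folds: int = 5,
    n_genes: int = 20000,
    n_pc: int = 220,
    min_cells: int = 100,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Each fold normalizes, fits the model on its training cells only, and
    predicts its held-out cells; five folds realize the 80-20 train/test
    ratio.  The pooled confusion matrix and per-fold macro F1 scores are
    returned; the mean fold score is the headline.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    matrix = filter_rare_types(matrix, label_key, min_cells=min_cells)
    labels = matrix.require_meta(label_key).astype(str).to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {uniq[counts.argmin()]!r} has fewer cells than folds={folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores, all_truth, all_pred = [], [], []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        train = matrix.subset_cells(train_idx)
        test = matrix.subset_cells(test_idx)
        model = fit_denoise_model(
            rank_zscore(train), labels[train_idx], n_genes=n_genes, n_pc=n_pc, seed=seed
        )
        pred = predict_types(model, rank_zscore(test))
        fold_scores.append(macro_f1(labels[test_idx], pred).macro_f1)
        all_truth.append(labels[test_idx])
        all_pred.append(pred)
    pooled = macro_f1(np.concatenate(all_truth), np.concatenate(all_pred))
    pooled.n_folds = folds
    pooled.fold_scores = fold_scores
    pooled.macro_f1 = float(np.mean(fold_scores))
    logger.info("crossvalidate seed=%d folds=%d scores=%s", seed, folds, fold_scores)
    return pooled
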