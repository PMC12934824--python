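"""PMI-based transcription-factor / gene co-expression enrichment.

For each transcription factor, the cells with high TF activity (top decile
of the TF's within-cell rank z-score by default) are compared against the
whole dataset: a gene's detection probability conditional on high TF
activity, p_cond = k / n_high, is set against its marginal detection
probability p_marg, giving a pointwise-mutual-information score

    PMI = log2(p_cond / p_marg).

Significance comes from a binomial null in which detections among the
TF-high cells occur at the marginal rate: Z = (k - n p) / sqrt(n p (1 - p)),
with a two-sided normal tail (exact binomial tail when the expected count
n * p is below 5), followed by Benjamini-Hochberg FDR correction across all
(TF, gene) pairs jointly.  Detection means raw count > 0; the TF-high cells
are not excluded from the marginal, and a TF is never tested against
itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binom, norm

from .io import ExpressionMatrix
from .normalization import NormalizedMatrix

__all__ = [
    "EnrichmentResult",
    "select_tf_high",
    "pmi_scores",
    "bh_fdr",
    "validate_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    tf: str
    gene: str
    n_high: int
    k_cond: int
    p_cond: float
    p_marg: float
    pmi: float
    z: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False


def select_tf_high(
    z: NormalizedMatrix, tf: str, top_fraction: float = 0.10
) -> np.ndarray:
    """Indices of cells whose normalized TF value is in the top fraction.

    The cutoff is the value ranked ceil(top_fraction * n) from the top;
    boundary ties are all included.  A TF with no expression variation
    across cells cannot define a high-activity set and is rejected.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    vals = z.gene_column(tf)
    if np.ptp(vals) == 0:
        raise ValueError(f"TF {tf!r} has no expression variation")
    n_top = max(1, int(np.ceil(top_fraction * len(vals))))
    cutoff = np.sort(vals)[::-1][n_top - 1]
    return np.flatnonzero(vals >= cutoff)


def pmi_scores(
    matrix: ExpressionMatrix,
    z: NormalizedMatrix,
    tfs,
    alpha: float = 0.05,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """PMI enrichment of every gene's detection in each TF's high-activity cells.

    Returns one row per testable (TF, gene) pair with PMI, Z, p, BH-adjusted
    q (computed jointly across all pairs), and a significance flag at
    ``q < alpha``.  Pairs whose marginal detection probability is 0 or 1 are
    skipped (the statistic is undefined); skips are logged with a reason.
    """
    if matrix.n_cells < 30:
        raise ValueError("need at least 30 cells for enrichment statistics")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids.astype(str))}
    missing = [t for t in tfs if t not in gene_pos]
    if missing:
        raise KeyError(f"TF {missing[0]!r} not among genes")
    detected = (matrix.counts > 0).toarray() if sp.issparse(matrix.counts) else matrix.counts > 0
    n_cells = matrix.n_cells
    p_marg = detected.mean(axis=0)
    rows = []
    for tf in tfs:
        high = select_tf_high(z, tf, top_fraction=top_fraction)
        n_high = len(high)
        k = detected[high].sum(axis=0)
        for j, gene in enumerate(matrix.gene_ids.astype(str)):
            if gene == tf:
                continue
            pm = p_marg[j]
            if pm == 0.0 or pm == 1.0:
                logger.debug("skipping (%s, %s): degenerate marginal %.0f", tf, gene, pm)
                continue
            pc = k[j] / n_high
            with np.errstate(divide="ignore"):
                pmi = float(np.log2(pc / pm)) if pc > 0 else -np.inf
            mean = n_high * pm
            sd = np.sqrt(n_high * pm * (1 - pm))
            zstat = (k[j] - mean) / sd
            if mean < 5:
                pval = 2 * min(binom.cdf(k[j], n_high, pm), binom.sf(k[j] - 1, n_high, pm))
                pval = min(1.0, float(pval))
            else:
                pval = float(2 * norm.sf(abs(zstat)))
            rows.append(
                dict(
                    tf=tf, gene=gene, n_high=n_high, k_cond=int(k[j]),
                    p_cond=float(pc), p_marg=float(pm), pmi=pmi,
                    z=float(zstat), p_value=pval,
                )
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no testable (TF, gene) pairs")
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or not len(p):
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def validate_enrichment(results: pd.DataFrame, truth_pairs) -> dict:
    """Fold enrichment of significant calls in a (tf, gene) truth set.

    fold = (fraction of significant pairs in truth) /
           (fraction of all tested pairs in truth).
    With zero significant pairs the fold is undefined (NaN) and only the
    counts are reported.
    """
    truth = {(str(a), str(b)) for a, b in truth_pairs}
    if not truth:
        raise ValueError("truth_pairs is empty")
    tested = list(zip(results["tf"].astype(str), results["gene"].astype(str)))
    in_truth = np.array([pair in truth for pair in tested])
    sig = results["significant"].to_numpy()
    n_sig = int(sig.sum())
    n_sig_truth = int((sig & in_truth).sum())
    base_rate = in_truth.mean()
    if n_sig == 0:
        fold = np.nan
    elif base_rate == 0:
        fold = np.nan
    else:
        fold = (n_sig_truth / n_sig) / base_rate
    return dict(
        fold_enrichment=float(fold) if fold == fold else np.nan,
        n_significant=n_sig,
        n_significant_in_truth=n_sig_truth,
        n_tested=len(tested),
        n_tested_in_truth=int(in_truth.sum()),
    )
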