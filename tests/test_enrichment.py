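import numpy as np
import pandas as pd
import pytest

from plaincell.enrichment import bh_fdr, pmi_scores, select_tf_high, validate_enrichment
from plaincell.normalization import NormalizedMatrix, rank_zscore
from plaincell.simulate import TFNetSpec, simulate_tf_network
from conftest import make_matrix


def _z_with_tf_column(tf_z):
    """NormalizedMatrix whose TF column carries the given per-cell z values."""
    tf_z = np.asarray(tf_z, dtype=float)
    n = len(tf_z)
    filler = np.zeros((n, 2))
    z = np.column_stack([tf_z, filler])
    return NormalizedMatrix(z, np.array([f"c{i}" for i in range(n)], dtype=object),
                            np.array(["TF", "g0", "g1"], dtype=object))


def _rank_preserving_matrix(tf_counts, extra_cols):
    """Counts where the TF's within-cell rank is monotone in its own count.

    Filler genes carry the same even counts in every cell; TF counts are odd,
    so a cell's TF z is strictly increasing in its TF count across cells.
    """
    tf_counts = np.asarray(tf_counts)
    n = len(tf_counts)
    n_filler = int(tf_counts.max() // 2) + 2
    filler = np.tile(2 * np.arange(1, n_filler + 1), (n, 1))
    counts = np.column_stack([tf_counts, extra_cols, filler])
    names = (["TF"] + [f"x{j}" for j in range(np.atleast_2d(extra_cols.T).shape[0])]
             + [f"f{j}" for j in range(n_filler)])
    return make_matrix(counts, gene_ids=names)


class TestSelectTfHigh:
    def test_top_decile_of_distinct_values(self):
        z = _z_with_tf_column(np.arange(100))
        idx = select_tf_high(z, "TF", top_fraction=0.10)
        assert sorted(idx) == list(range(90, 100))

    def test_half_of_four_distinct_values(self):
        z = _z_with_tf_column([0.1, 0.2, 0.3, 0.4])
        idx = select_tf_high(z, "TF", top_fraction=0.5)
        assert sorted(idx) == [2, 3]

    def test_constant_tf_rejected(self):
        z = _z_with_tf_column(np.full(50, 0.7))
        with pytest.raises(ValueError, match="no expression variation"):
            select_tf_high(z, "TF")

    def test_boundary_ties_all_included(self):
        z = _z_with_tf_column([0.0] * 5 + [0.5] * 3 + [0.9] * 2)
        idx = select_tf_high(z, "TF", top_fraction=0.3)
        assert sorted(idx) == [5, 6, 7, 8, 9]  # ties at the cutoff kept


class TestPmiScores:
    def test_hand_worked_enrichment(self):
        # 250 cells; TF-high = top 50 by TF count; gene detected in 20 of
        # them and 30 others: p_cond = 0.4, p_marg = 0.2 -> PMI = 1,
        # Z = (20 - 10) / sqrt(50 * 0.2 * 0.8) = 3.5355
        n = 250
        tf = 2 * np.arange(n) + 1  # distinct odd counts; top 50 are cells 200..249
        gene = np.zeros(n)
        gene[200:220] = 1  # 20 detections among TF-high
        gene[:30] = 1      # 30 among the rest
        m = _rank_preserving_matrix(tf, gene[:, None])
        res = pmi_scores(m, rank_zscore(m), ["TF"], top_fraction=0.2)
        row = res[res.gene == "x0"].iloc[0]
        assert row.n_high == 50 and row.k_cond == 20
        np.testing.assert_allclose(row.p_cond, 0.4)
        np.testing.assert_allclose(row.p_marg, 0.2)
        np.testing.assert_allclose(row.pmi, 1.0)
        np.testing.assert_allclose(row.z, 3.5355339, atol=1e-6)

    def test_ubiquitous_gene_skipped(self):
        rng = np.random.default_rng(2)
        counts = np.column_stack([np.arange(40), np.ones(40), rng.poisson(1.0, size=(40, 2))])
        m = make_matrix(counts, gene_ids=["TF", "always", "f1", "f2"])
        res = pmi_scores(m, rank_zscore(m), ["TF"])
        assert "always" not in set(res.gene)

    def test_tf_not_tested_against_itself(self):
        m = _rank_preserving_matrix(2 * np.arange(60) + 1,
                                    np.random.default_rng(1).poisson(1.0, size=(60, 2)))
        res = pmi_scores(m, rank_zscore(m), ["TF"])
        assert "TF" not in set(res.gene)

    def test_conditioning_on_all_cells_gives_zero_scores(self):
        rng = np.random.default_rng(3)
        counts = np.column_stack([np.arange(50), rng.poisson(1.0, size=(50, 4))])
        m = make_matrix(counts, gene_ids=["TF"] + [f"g{j}" for j in range(4)])
        res = pmi_scores(m, rank_zscore(m), ["TF"], top_fraction=0.999)
        assert (res.n_high == 50).all()
        np.testing.assert_allclose(res.pmi, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.z, 0.0, atol=1e-12)


class TestBhFdr:
    def test_worked_examples(self):
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 1.0]),
                                   [0.04, 0.04, 0.04, 1.0])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_step_up_and_preserves_order(self, rng):
        def brute(p):
            # literal step-up definition: q_(i) = min_{j >= i} p_(j) * m / j
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            sorted_p = p[order]
            q_sorted = [
                min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)
            ]
            q = np.empty(m)
            q[order] = q_sorted
            return q

        for _ in range(200):
            p = rng.random(rng.integers(1, 21))
            mine = bh_fdr(p)
            np.testing.assert_allclose(mine, brute(p), atol=1e-12)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(mine[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50)
        np.testing.assert_allclose(bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestValidateEnrichment:
    @staticmethod
    def _results(sig_pairs, all_pairs):
        return pd.DataFrame(
            {
                "tf": [a for a, _ in all_pairs],
                "gene": [b for _, b in all_pairs],
                "significant": [p in sig_pairs for p in all_pairs],
            }
        )

    def test_truth_equals_all_tested_gives_fold_one(self):
        pairs = [("t", f"g{i}") for i in range(10)]
        res = self._results(set(pairs[:3]), pairs)
        assert validate_enrichment(res, pairs)["fold_enrichment"] == 1.0

    def test_disjoint_truth_gives_zero_fold(self):
        pairs = [("t", f"g{i}") for i in range(10)]
        out = validate_enrichment(self._results({pairs[0]}, pairs), [("t", "g9")])
        assert out["fold_enrichment"] == 0.0
        assert out["n_significant_in_truth"] == 0

    def test_no_significant_pairs_reports_counts_only(self):
        pairs = [("t", f"g{i}") for i in range(4)]
        out = validate_enrichment(self._results(set(), pairs), [pairs[0]])
        assert np.isnan(out["fold_enrichment"])
        assert out["n_tested"] == 4


def test_null_effect_makes_planted_edges_indistinguishable():
    sig_frac = []
    for seed in range(5):
        m, edges = simulate_tf_network(TFNetSpec(effect_logit_shift=0.0, n_cells=400,
                                                 n_genes=120, seed=seed))
        res = pmi_scores(m, rank_zscore(m), sorted({t for t, _ in edges}))
        sig_frac.append(res.significant.mean())
    assert np.mean(sig_frac) <= 0.05 + 0.03
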