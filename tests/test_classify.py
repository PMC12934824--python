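import itertools

import numpy as np
import pytest

from plaincell.classify import (
    anova_f_statistic,
    anova_select,
    crossvalidate,
    filter_rare_types,
    fit_denoise_model,
    macro_f1,
    predict_types,
)
from plaincell.normalization import NormalizedMatrix, rank_zscore
from plaincell.simulate import simulate_tissue
from conftest import make_matrix


def _znm(z):
    z = np.asarray(z, dtype=float)
    return NormalizedMatrix(z, np.array([f"c{i}" for i in range(z.shape[0])], dtype=object),
                            np.array([f"g{j}" for j in range(z.shape[1])], dtype=object))


def _brute_force_f(col, labels):
    """Textbook two-loop one-way F: MSB / MSW."""
    groups = [col[labels == g] for g in np.unique(labels)]
    N, G = len(col), len(groups)
    grand = col.mean()
    msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (G - 1)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - G)
    if msw == 0:
        return np.inf if msb > 0 else 0.0
    return msb / msw


class TestFilterRareTypes:
    def test_small_class_removed(self, rng):
        labels = ["A"] * 150 + ["B"] * 99
        m = make_matrix(rng.poisson(1.0, size=(249, 5)), {"cell_type": labels})
        out = filter_rare_types(m, "cell_type", min_cells=100)
        assert out.n_cells == 150
        assert set(out.cell_meta["cell_type"]) == {"A"}

    @pytest.mark.parametrize("min_cells", [1, 50])
    def test_identity_when_all_classes_large_enough(self, rng, min_cells):
        m = make_matrix(rng.poisson(1.0, size=(120, 5)),
                        {"cell_type": ["A"] * 60 + ["B"] * 60})
        assert filter_rare_types(m, "cell_type", min_cells=min_cells).n_cells == 120

    def test_nothing_surviving_rejected(self, rng):
        m = make_matrix(rng.poisson(1.0, size=(4, 5)), {"cell_type": list("ABAB")})
        with pytest.raises(ValueError, match="at least 100"):
            filter_rare_types(m, "cell_type", min_cells=100)


class TestAnova:
    def test_hand_worked_two_group_example(self):
        # groups (1,2) vs (3,4): grand mean 2.5, group means 1.5 / 3.5
        # SSB = 2*1 + 2*1 = 4 -> MSB = 4/(2-1) = 4
        # SSW = 4 * 0.25 = 1 -> MSW = 1/(4-2) = 0.5, so F = 8
        col = np.array([[1.0], [2.0], [3.0], [4.0]])
        labels = np.array(["a", "a", "b", "b"])
        F = anova_f_statistic(col, labels)
        np.testing.assert_allclose(F[0], _brute_force_f(col[:, 0], labels), atol=1e-12)
        np.testing.assert_allclose(F[0], 8.0, atol=1e-12)

    def test_constant_gene_scores_zero_and_separated_gene_ranks_first(self):
        X = np.array([[1.0, 5.0, 1.0], [1.0, 5.0, 1.0], [3.0, 5.0, 1.2], [3.0, 5.0, 0.8]])
        labels = np.array(["a", "a", "b", "b"])
        F = anova_f_statistic(X, labels)
        assert F[0] == np.inf  # zero within-variance, positive between
        assert F[1] == 0.0     # constant everywhere
        sel = anova_select(_znm(X), labels, n_genes=1)
        assert list(sel) == [0]

    def test_matches_brute_force_on_random_fixture(self, rng):
        X = rng.normal(size=(40, 50))
        labels = rng.choice(["a", "b", "c"], size=40)
        F = anova_f_statistic(X, labels)
        expected = [_brute_force_f(X[:, j], labels) for j in range(50)]
        np.testing.assert_allclose(F, expected, atol=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            anova_f_statistic(np.ones((2, 3)), np.array(["a", "b"]))

    def test_boundary_ties_keep_lower_gene_index(self):
        X = np.tile(np.array([[0.0], [0.0], [1.0], [1.0]]), (1, 4))
        labels = np.array(["a", "a", "b", "b"])
        sel = anova_select(_znm(X), labels, n_genes=2)
        assert list(sel) == [0, 1]


class TestMacroF1:
    def test_perfect_prediction(self):
        assert macro_f1(list("AABB"), list("AABB")).macro_f1 == 1.0

    def test_half_crossed_two_class(self):
        rep = macro_f1(list("AABB"), list("ABAB"))
        assert rep.per_class_f1 == {"A": 0.5, "B": 0.5}
        assert rep.macro_f1 == 0.5

    def test_never_predicted_class_contributes_zero(self):
        rep = macro_f1(list("AABB"), list("AAAA"))
        assert rep.per_class_f1["B"] == 0.0
        np.testing.assert_allclose(rep.macro_f1, (2 / 3 + 0.0) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            macro_f1(["A"], ["A", "B"])

    def test_exhaustive_three_class_agreement_with_sklearn(self):
        from sklearn.metrics import f1_score

        truth = np.array(list("ABCABC"))
        labels = np.unique(truth)
        for pred in itertools.product("ABC", repeat=6):
            mine = macro_f1(truth, np.array(pred)).macro_f1
            ref = f1_score(truth, np.array(pred), labels=labels, average="macro",
                           zero_division=0)
            np.testing.assert_allclose(mine, ref, atol=1e-12)


class TestDenoiseModel:
    @pytest.fixture()
    def separable(self, rng):
        m, _ = simulate_tissue(n_types=3, n_genes=300, cells_per_type=(60, 80),
                               batch_sd=0.1, seed=7)
        return m

    def test_training_f1_perfect_on_separable_fixture(self, separable):
        z = rank_zscore(separable)
        y = separable.cell_meta["cell_type"].to_numpy()
        model = fit_denoise_model(z, y, n_genes=200, n_pc=10)
        assert macro_f1(y, predict_types(model, z)).macro_f1 == 1.0

    def test_n_pc_clipped_to_rank_bound(self, separable, caplog):
        z = rank_zscore(separable)
        y = separable.cell_meta["cell_type"].to_numpy()
        model = fit_denoise_model(z, y, n_genes=50, n_pc=500)
        assert model.pca_components.shape[1] == 50
        # columns orthonormal
        G = model.pca_components.T @ model.pca_components
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_refit_is_deterministic(self, separable):
        z = rank_zscore(separable)
        y = separable.cell_meta["cell_type"].to_numpy()
        m1 = fit_denoise_model(z, y, n_genes=100, n_pc=10, seed=0)
        m2 = fit_denoise_model(z, y, n_genes=100, n_pc=10, seed=0)
        np.testing.assert_array_equal(m1.selected_genes, m2.selected_genes)
        np.testing.assert_array_equal(predict_types(m1, z), predict_types(m2, z))

    def test_shuffled_test_gene_order_gives_identical_predictions(self, separable, rng):
        z = rank_zscore(separable)
        y = separable.cell_meta["cell_type"].to_numpy()
        model = fit_denoise_model(z, y, n_genes=100, n_pc=10)
        perm = rng.permutation(z.n_genes)
        shuffled = NormalizedMatrix(z.z[:, perm], z.cell_ids, z.gene_ids[perm])
        np.testing.assert_array_equal(predict_types(model, shuffled),
                                      predict_types(model, z))

    def test_single_class_rejected(self, rng):
        z = _znm(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError, match="2 classes"):
            fit_denoise_model(z, ["A"] * 10)


class TestCrossvalidate:
    def test_separable_fixture_scores_one(self):
        m, _ = simulate_tissue(n_types=3, n_genes=300, cells_per_type=(120, 150),
                               batch_sd=0.1, seed=1)
        rep = crossvalidate(m, "cell_type", folds=5, n_genes=200, n_pc=10, min_cells=100)
        assert rep.macro_f1 == 1.0
        assert rep.n_folds == 5 and len(rep.fold_scores) == 5

    def test_uninformative_labels_score_at_chance(self, rng):
        scores = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            m = make_matrix(r.poisson(2.0, size=(160, 60)),
                            {"cell_type": r.choice(["A", "B"], size=160)})
            rep = crossvalidate(m, "cell_type", folds=4, n_genes=40, n_pc=5,
                                min_cells=1, seed=seed)
            scores.append(rep.macro_f1)
        assert 0.4 <= np.mean(scores) <= 0.6

    def test_single_fold_rejected(self, rng):
        m = make_matrix(rng.poisson(2.0, size=(20, 5)),
                        {"cell_type": ["A", "B"] * 10})
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(m, "cell_type", folds=1, min_cells=1)


def test_rank_pipeline_beats_log_cpm_under_batch_distortion():
    """Regression guard: with strong per-batch amplification distortion the
    rank-based normalization outperforms library-size log-normalization."""
    gaps = []
    for seed in range(5):
        m, _ = simulate_tissue(n_types=8, n_genes=400, cells_per_type=(100, 140),
                               batch_sd=1.0, markers_per_type=8, marker_boost=0.7,
                               type_sd=0.15, seed=seed)
        y = m.cell_meta["cell_type"].to_numpy()
        r = np.random.default_rng(seed)
        idx = r.permutation(m.n_cells)
        cut = int(0.8 * m.n_cells)
        tr, te = idx[:cut], idx[cut:]
        mtr, mte = m.subset_cells(tr), m.subset_cells(te)

        def score(make_norm):
            model = fit_denoise_model(make_norm(mtr), y[tr], n_genes=300, n_pc=15, seed=seed)
            return macro_f1(y[te], predict_types(model, make_norm(mte))).macro_f1

        def log_cpm(mat):
            dense = mat.counts.toarray().astype(float)
            tot = dense.sum(axis=1, keepdims=True)
            tot[tot == 0] = 1.0
            return NormalizedMatrix(np.log1p(dense / tot * 1e4), mat.cell_ids, mat.gene_ids)

        gaps.append(score(rank_zscore) - score(log_cpm))
    assert np.mean(gaps) > 0
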