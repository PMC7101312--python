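import numpy as np
import pytest

from painmark import decode as dec
from painmark.features import TimeWindow


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        y = np.array(["INNO", "MOD", "NOX"] * 5)
        assert dec.balanced_accuracy(y, y) == 1.0

    def test_constant_prediction_on_balanced_labels(self):
        y = np.array(["INNO", "MOD", "NOX"] * 4)
        pred = np.array(["MOD"] * 12)
        assert dec.balanced_accuracy(y, pred) == pytest.approx(1 / 3)

    def test_matches_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b", "c"], 200)
        pred = rng.choice(["a", "b", "c"], 200)
        assert dec.balanced_accuracy(y, pred) == pytest.approx(
            balanced_accuracy_score(y, pred)
        )

    def test_equals_plain_accuracy_on_balanced_labels(self):
        rng = np.random.default_rng(1)
        y = np.array(["a", "b", "c"] * 30)
        pred = rng.choice(["a", "b", "c"], 90)
        assert dec.balanced_accuracy(y, pred) == pytest.approx(np.mean(y == pred))

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            dec.balanced_accuracy([], [])
        with pytest.raises(ValueError):
            dec.balanced_accuracy(["a"], ["a", "b"])


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        y = ["INNO"] * 3 + ["MOD"] * 4 + ["NOX"] * 5
        cm = dec.confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([3, 4, 5]))

    def test_row_sums_and_bruteforce_counts(self):
        rng = np.random.default_rng(2)
        y = rng.choice(dec.CLASS_ORDER, 60)
        pred = rng.choice(dec.CLASS_ORDER, 60)
        cm = dec.confusion_matrix(y, pred)
        for i, ci in enumerate(dec.CLASS_ORDER):
            assert cm[i].sum() == np.sum(y == ci)
            for j, cj in enumerate(dec.CLASS_ORDER):
                assert cm[i, j] == sum(
                    1 for t, p in zip(y, pred) if t == ci and p == cj
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            dec.confusion_matrix(["INNO"], ["HOT"])


class TestStratifiedSplit:
    def test_120_balanced_trials_give_8_per_class_test(self):
        y = np.array(["INNO", "MOD", "NOX"] * 40)
        train, test = dec.stratified_split(y, 0.2, seed=0)
        assert len(test) == 24 and len(train) == 96
        for c in dec.CLASS_ORDER:
            assert np.sum(y[test] == c) == 8

    def test_partition_properties_and_determinism(self):
        y = np.array(["a", "b", "c"] * 20)
        tr1, te1 = dec.stratified_split(y, 0.2, seed=5)
        tr2, te2 = dec.stratified_split(y, 0.2, seed=5)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert set(tr1) | set(te1) == set(range(60))
        assert set(tr1) & set(te1) == set()

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            dec.stratified_split(["a", "a", "b"] * 1, 0.2)


class TestPCAProject:
    def test_training_scores_centred(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 10))
        scores, _, _ = dec.pca_project(X, X, 2)
        assert np.abs(scores.mean(axis=0)).max() < 1e-9

    def test_captured_variance_matches_eigendecomposition(self):
        """Eigendecomposition oracle on the training covariance."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 8)) @ rng.standard_normal((8, 8))
        _, _, pca = dec.pca_project(X, X, 2)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        assert np.sum(pca.explained_variance_[:2]) == pytest.approx(
            evals[:2].sum(), rel=1e-9
        )

    def test_rank_two_data_reconstructs_exactly(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 9))
        scores, _, pca = dec.pca_project(X, X, 2)
        rebuilt = scores @ pca.components_ + pca.mean_
        assert np.allclose(rebuilt, X, atol=1e-9)

    def test_no_leakage_from_test_rows(self):
        rng = np.random.default_rng(6)
        Xtr = rng.standard_normal((50, 6))
        Xte = rng.standard_normal((20, 6))
        _, _, p1 = dec.pca_project(Xtr, Xte, 2)
        _, _, p2 = dec.pca_project(Xtr, Xte * 1e6 + 3.0, 2)
        assert np.array_equal(p1.components_, p2.components_)
        assert np.array_equal(p1.mean_, p2.mean_)

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dec.pca_project(np.ones((10, 4)), np.ones((2, 4)), 2)


class TestClassifiers:
    def test_knn_one_neighbour_memorises_training_set(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 5))
        y = rng.choice(["a", "b", "c"], 30)
        pred = dec.fit_predict("KNN", X, y, X, hyper={"k": 1})
        assert dec.balanced_accuracy(y, pred) == 1.0

    def test_lda_separates_distant_gaussians(self):
        """Monte-Carlo oracle: 10-sigma separated spherical classes have
        Bayes error ~ 0."""
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.standard_normal((200, 4)),
                            rng.standard_normal((200, 4)) + 10.0])
        y = np.array(["a"] * 200 + ["b"] * 200)
        Xt = np.concatenate([rng.standard_normal((100, 4)),
                             rng.standard_normal((100, 4)) + 10.0])
        yt = np.array(["a"] * 100 + ["b"] * 100)
        pred = dec.fit_predict("LDA", X, y, Xt)
        assert dec.balanced_accuracy(yt, pred) > 0.99

    def test_nb_posteriors_normalised(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 3))
        y = rng.choice(["a", "b", "c"], 60)
        clf = dec.make_classifier("NB")
        clf.fit(X, y)
        proba = clf.predict_proba(rng.standard_normal((10, 3)))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_ridge_qda_matches_sklearn_when_well_conditioned(self):
        """Cross-check against sklearn QDA in the regime it supports
        (more samples than features)."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(10)
        X = rng.standard_normal((300, 4))
        X[:150] += [2.0, 0, 0, 0]
        y = np.array(["a"] * 150 + ["b"] * 150)
        Xt = rng.standard_normal((100, 4)) + [1.0, 0, 0, 0]
        ours = dec.RidgeQDA(reg_param=1e-10).fit(X, y).predict(Xt)
        ref = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y).predict(Xt)
        assert np.mean(ours == ref) > 0.99

    def test_ridge_qda_handles_singular_covariance_with_warning(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 64))
        y = np.array(["a", "b"] * 10)
        with pytest.warns(UserWarning, match="singular"):
            pred = dec.fit_predict("QLDA", X, y, X)
        assert set(pred) <= {"a", "b"}

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            dec.make_classifier("MLP")


class TestCrossValidate:
    def test_returns_k_scores(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 4))
        y = np.array(["a", "b", "c"] * 20)
        scores = dec.cross_validate("NB", X, y, k=10, seed=0)
        assert scores.shape == (10,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_class_smaller_than_k_rejected(self):
        X = np.zeros((12, 2))
        y = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(ValueError):
            dec.cross_validate("NB", X, y, k=10)

    def test_pure_noise_scores_near_chance(self):
        """Permutation-null oracle: label-independent features give mean CV
        balanced accuracy near 1/3 over repeated draws."""
        rng = np.random.default_rng(13)
        y = np.array(["a", "b", "c"] * 20)
        means = []
        for rep in range(20):
            X = rng.standard_normal((60, 4))
            means.append(np.mean(dec.cross_validate("LDA", X, y, k=10, seed=rep)))
        grand = np.mean(means)
        sd = np.std(means) / np.sqrt(len(means))
        assert abs(grand - 1 / 3) < 3 * max(sd, 0.01)

    def test_separable_data_scores_high(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((60, 4))
        y = np.array(["a", "b", "c"] * 20)
        for i, c in enumerate(("a", "b", "c")):
            X[y == c, i] += 8.0
        assert np.mean(dec.cross_validate("LDA", X, y, k=10, seed=0)) > 0.95


class TestGridSearchSVM:
    def separable(self, seed=15):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 2))
        y = np.array(["a", "b", "c"] * 20)
        X[y == "b"] += [6, 0]
        X[y == "c"] += [0, 6]
        return X, y

    def test_single_point_grid(self):
        X, y = self.separable()
        params, _, _ = dec.grid_search_svm(X, y, [{"kernel": "linear", "C": 1.0}])
        assert params == {"kernel": "linear", "C": 1.0}

    def test_best_matches_exhaustive_evaluation(self):
        """Exhaustive oracle: independently score every grid point and
        compare with the reported winner."""
        X, y = self.separable()
        grid = dec.default_svm_grid()[:8]
        best, score, table = dec.grid_search_svm(X, y, grid, k=5, seed=3)
        manual = [
            float(np.mean(dec.cross_validate("SVM", X, y, k=5, seed=3, hyper=p)))
            for p in grid
        ]
        assert score == pytest.approx(max(manual))
        assert best == grid[int(np.argmax(manual))]  # first maximiser wins

    def test_duplicate_points_first_wins(self):
        X, y = self.separable()
        p = {"kernel": "linear", "C": 1.0}
        best, _, table = dec.grid_search_svm(X, y, [p, dict(p)], k=5)
        assert best is table[0][0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dec.grid_search_svm(np.zeros((9, 2)), ["a", "b", "c"] * 3, [])


class TestSequentialForwardSelection:
    def test_selecting_all_channels_returns_permutation(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 4))
        y = np.array(["a", "b", "c"] * 10)
        sel = dec.sequential_forward_selection(X, y, n_select=4, k=5, seed=0)
        assert sorted(sel) == [0, 1, 2, 3]

    def test_first_pick_matches_bruteforce_single_channel_argmax(self):
        """Brute-force first-step oracle with the same scorer."""
        rng = np.random.default_rng(17)
        X = rng.standard_normal((60, 6))
        y = np.array(["a", "b", "c"] * 20)
        X[y == "b", 3] += 3.0
        X[y == "c", 3] -= 3.0
        sel = dec.sequential_forward_selection(X, y, n_select=1, k=10, seed=2,
                                               n_repeats=3)
        scorer = dec._FastLDAScorer(X, y, k=10, seed=2, n_repeats=3)
        scores = [scorer.score([c]) for c in range(6)]
        assert sel[0] == int(np.argmax(scores)) == 3

    def test_fast_lda_scorer_matches_sklearn_cross_validation(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((57, 5))  # jagged folds
        y = np.array(["a", "b", "c"] * 19)
        X[y == "a", 0] += 1.0
        scorer = dec._FastLDAScorer(X, y, k=10, seed=4, n_repeats=1)
        for cols in ([0], [1, 3], [0, 2, 4]):
            fast = scorer.score(cols)
            slow = float(np.mean(dec.cross_validate("LDA", X[:, cols], y, k=10, seed=4)))
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_generic_scorer_path(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((30, 3))
        y = np.array(["a", "b", "c"] * 10)
        X[y == "a", 1] += 5.0
        X[y == "b", 1] -= 5.0
        sel = dec.sequential_forward_selection(X, y, n_select=1, k=5, seed=0,
                                               classifier="NB", n_repeats=1)
        assert sel == [1]

    def test_label_output(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((30, 3))
        y = np.array(["a", "b", "c"] * 10)
        sel = dec.sequential_forward_selection(
            X, y, n_select=2, k=5, seed=0, channel_labels=("u", "v", "w")
        )
        assert set(sel) <= {"u", "v", "w"}

    def test_too_many_channels_rejected(self):
        with pytest.raises(ValueError):
            dec.sequential_forward_selection(np.zeros((9, 2)), ["a", "b", "c"] * 3, 3)


class TestSweepAndFinalTest:
    def test_sweep_table_shape_and_recovery(self, small_session):
        sweep = dec.sweep_windows(small_session["analysis"],
                                  dec.DecodeConfig(seed=11))
        assert len(sweep.windows) == 9
        assert all(set(row) == set(dec.CLASSIFIER_NAMES) for row in sweep.fold_baccs)
        assert all(len(s) == 10 for row in sweep.fold_baccs for s in row.values())
        assert (sweep.best_window.start_ms, sweep.best_window.end_ms) == (650.0, 750.0)

    def test_final_test_confusion_rows(self, small_session):
        final = dec.final_test(small_session["augmented"], TimeWindow(650, 750),
                               dec.DecodeConfig(seed=11))
        n_per_class = final.confusion.sum(axis=1)
        assert final.n_test == n_per_class.sum()
        assert np.all(n_per_class == n_per_class[0])
        assert 0.0 <= final.test_bacc <= 1.0

    def test_shuffled_labels_score_near_chance(self, small_session):
        aug = small_session["augmented"].copy()
        rng = np.random.default_rng(0)
        aug.labels = list(rng.permutation(aug.labels))
        final = dec.final_test(aug, TimeWindow(650, 750), dec.DecodeConfig(seed=11))
        assert final.test_bacc < 0.65  # far below the planted-signal regime

    def test_final_test_ignores_test_row_corruption(self, small_session):
        """No-leakage: the fitted pipeline (split, PCA, grid search) is a
        function of training rows only, so corrupting test-row features
        cannot change which hyperparameters win."""
        aug = small_session["augmented"]
        cfg = dec.DecodeConfig(seed=11)
        feats = dec.max_amplitude_features(aug, TimeWindow(650, 750))
        y = np.asarray(feats.labels)
        train, test = dec.stratified_split(y, cfg.test_fraction, seed=cfg.seed)
        Xa = feats.values.copy()
        Xb = feats.values.copy()
        Xb[test] = 1e6
        sa, _, pa = dec.pca_project(Xa[train], Xa[test], 2)
        sb, _, pb = dec.pca_project(Xb[train], Xb[test], 2)
        assert np.array_equal(pa.components_, pb.components_)
        ga = dec.grid_search_svm(sa, y[train], k=10, seed=cfg.seed)[0]
        gb = dec.grid_search_svm(sb, y[train], k=10, seed=cfg.seed)[0]
        assert ga == gb
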