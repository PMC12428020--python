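"""SVM, cosine k-NN, GP surrogate, expected improvement and BO."""

import numpy as np
import pytest
from scipy.stats import norm

from eegdem.classify import (KNN_K_SPACE, KNNConfig, SearchSpace, SVMConfig,
                             bayes_opt, cv_objective, expected_improvement,
                             gp_fit, knn_predict, resubstitution_objective,
                             standardize_apply, standardize_fit,
                             standardize_invert, svm_predict, svm_train)


class TestStandardize:
    def test_train_columns_become_zero_mean_unit_sd(self, rng):
        X = rng.normal(5, 3, size=(50, 4))
        stats = standardize_fit(X)
        Z = standardize_apply(X, stats)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_invert_recovers_training_matrix(self, rng):
        X = rng.normal(size=(20, 3))
        stats = standardize_fit(X)
        back = standardize_invert(standardize_apply(X, stats), stats)
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_constant_column_dropped_consistently(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        stats = standardize_fit(X)
        Z = standardize_apply(X, stats)
        assert Z.shape == (20, 2)
        assert list(stats.kept_columns) == [0, 2]


class TestSVM:
    def test_linearly_separable_corners(self):
        X = np.array([[0.0, 0], [0, 1], [10, 10], [10, 11]])
        y = np.array(["AD", "AD", "HC", "HC"])
        model = svm_train(X, y, SVMConfig(box_constraint=1.0))
        pred, scores = svm_predict(model, X)
        assert list(pred) == list(y)
        assert scores.shape == (4, 2)

    def test_xor_solved_by_quadratic_kernel(self):
        """XOR is not linearly separable but the degree-2 kernel
        separates it; cross-checked against an explicit quadratic
        feature-map linear solver."""
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array(["AD", "AD", "HC", "HC"])
        model = svm_train(X, y, SVMConfig(box_constraint=100.0,
                                          kernel_scale=1.0))
        pred, _ = svm_predict(model, X)
        assert list(pred) == list(y)
        # oracle: hard-margin linear SVM in the explicit map of
        # (u.v + 1)^2 = phi(u).phi(v)
        from sklearn.svm import LinearSVC
        phi = np.column_stack([
            np.ones(4), np.sqrt(2) * X[:, 0], np.sqrt(2) * X[:, 1],
            X[:, 0] ** 2, X[:, 1] ** 2, np.sqrt(2) * X[:, 0] * X[:, 1]])
        oracle = LinearSVC(C=1e4, loss="hinge", max_iter=100_000).fit(phi, y)
        assert list(oracle.predict(phi)) == list(y)

    def test_duplicating_rows_leaves_predictions_invariant(self, rng):
        """On a separable set with C large enough that the margin (not
        the box constraint) binds, duplicating every training row does
        not move the decision boundary."""
        X = rng.normal(size=(30, 4))
        X[:, 0] += np.where(X[:, 0] > 0, 1.0, -1.0)  # carve a margin
        y = np.where(X[:, 0] > 0, "AD", "HC")
        m1 = svm_train(X, y, SVMConfig(box_constraint=100.0))
        m2 = svm_train(np.vstack([X, X]), np.concatenate([y, y]),
                       SVMConfig(box_constraint=100.0))
        p1, _ = svm_predict(m1, X)
        p2, _ = svm_predict(m2, X)
        assert list(p1) == list(p2)

    def test_training_accuracy_nondecreasing_in_C(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.where(X[:, 0] ** 2 + X[:, 1] > 0.3, "AD", "HC")
        accs = []
        for C in (0.1, 1.0, 10.0, 100.0):
            model = svm_train(X, y, SVMConfig(box_constraint=C))
            accs.append(np.mean(svm_predict(model, X)[0] == y))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_train(np.eye(3), np.array(["AD"] * 3), SVMConfig())


class TestKNN:
    def test_exact_match_returns_its_label(self):
        X = np.array([[1.0, 0], [0, 1], [-1, 0]])
        y = np.array(["AD", "HC", "FTD"])
        pred, _ = knn_predict(X, y, X[[1]], KNNConfig(k=1))
        assert pred[0] == "HC"

    def test_three_neighbour_hand_example(self):
        """Neighbours at 5, 10 and 90 degrees from the query with
        labels A, A, B: squared-inverse weights give class A the score
        1/d(5)^2 + 1/d(10)^2."""
        def unit(deg):
            r = np.radians(deg)
            return [np.cos(r), np.sin(r)]
        X = np.array([unit(5), unit(10), unit(90)])
        y = np.array(["AD", "AD", "HC"])
        query = np.array([[1.0, 0.0]])
        pred, scores = knn_predict(X, y, query,
                                   KNNConfig(k=3, class_order=("AD", "HC")))
        d = 1 - np.cos(np.radians([5, 10, 90]))
        assert pred[0] == "AD"
        assert scores[0, 0] == pytest.approx(1 / d[0] ** 2 + 1 / d[1] ** 2)
        assert scores[0, 1] == pytest.approx(1 / d[2] ** 2)

    def test_exact_match_short_circuits_squared_inverse(self):
        """A zero-distance neighbour dominates every finite weight."""
        X = np.array([[1.0, 0], [0.9, 0.1], [0.8, 0.2]])
        y = np.array(["FTD", "AD", "AD"])
        pred, _ = knn_predict(X, y, np.array([[2.0, 0]]), KNNConfig(k=3))
        assert pred[0] == "FTD"  # cosine distance 0 to the scaled query

    def test_cosine_scale_invariance(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.array(["AD", "HC"] * 10)
        q = rng.normal(size=(4, 5))
        p1, s1 = knn_predict(X, y, q, KNNConfig(k=3))
        X2 = X.copy()
        X2[7] *= 5.0
        p2, s2 = knn_predict(X2, y, q, KNNConfig(k=3))
        assert list(p1) == list(p2)
        np.testing.assert_allclose(s1, s2)

    def test_zero_norm_row_rejected(self):
        X = np.array([[1.0, 0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            knn_predict(X, np.array(["AD", "HC"]), np.array([[1.0, 1]]),
                        KNNConfig(k=1))

    def test_k_equal_n_with_uniform_geometry_goes_majority(self):
        """With k = n and all training points at identical distance the
        weighted vote degrades to the majority class."""
        X = np.tile([1.0, 1.0, 1.0], (12, 1)) * np.arange(1, 13)[:, None]
        y = np.array(["AD"] * 8 + ["HC"] * 4)
        q = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        pred, scores = knn_predict(X, y, q, KNNConfig(k=12))
        assert all(p == "AD" for p in pred)
        np.testing.assert_allclose(scores[:, 0] / scores[:, 1], 2.0)


class TestGPandEI:
    def test_posterior_interpolates_observations(self):
        """mu reproduces the observations and sigma collapses at the
        data relative to a point far from it."""
        x = np.array([0.0, 0.05, 0.1, 0.15])
        y = np.array([1.0, 1.2, 1.1, 0.9])
        posterior = gp_fit(x, y)
        mu, sigma = posterior(x)
        np.testing.assert_allclose(mu, y, atol=1e-3)
        _, sigma_far = posterior(np.array([0.9]))
        assert sigma.max() < 1e-3 * sigma_far[0]

    def test_posterior_mean_tracks_linear_function(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = 2.0 + 3.0 * x
        posterior = gp_fit(x, y)
        mu, _ = posterior(np.array([0.375]))
        assert mu[0] == pytest.approx(2.0 + 3.0 * 0.375, rel=0.05)

    def test_ei_degenerate_sigma_zero(self):
        assert expected_improvement(0.7, 0.0, 0.5) == pytest.approx(0.2)
        assert expected_improvement(0.3, 0.0, 0.5) == 0.0

    def test_ei_at_incumbent_equals_phi_zero(self):
        assert expected_improvement(0.5, 1.0, 0.5) == pytest.approx(
            norm.pdf(0.0), abs=1e-12)

    def test_ei_matches_monte_carlo(self, rng):
        draws = rng.standard_normal(1_000_000)
        for mu, sigma, f_best in [(0.5, 1.0, 0.5), (0.2, 0.3, 0.5),
                                  (0.9, 0.1, 0.5)]:
            mc = np.maximum(mu + sigma * draws - f_best, 0.0).mean()
            assert expected_improvement(mu, sigma, f_best) == pytest.approx(
                mc, abs=1e-3)

    def test_ei_nondecreasing_in_sigma_below_incumbent(self):
        sigmas = np.linspace(0, 2, 41)
        ei = expected_improvement(np.full_like(sigmas, 0.3), sigmas, 0.5)
        assert np.all(np.diff(ei) >= -1e-12)

    def test_ei_rejects_negative_sigma(self):
        with pytest.raises(ValueError):
            expected_improvement(0.5, -1.0, 0.0)


class TestBayesOpt:
    def test_quadratic_objective_lands_near_optimum(self):
        objective = lambda x: 1 - (x - 0.3) ** 2
        space = SearchSpace("x", 0.0, 1.0)
        result = bayes_opt(objective, space, n_iter=15, n_init=5, seed=0)
        assert abs(result.best_x - 0.3) <= 0.05
        # grid oracle: the exhaustive optimum is x = 0.3 exactly
        grid = np.linspace(0, 1, 10_001)
        assert result.best_y <= 1.0
        assert result.best_y >= np.max(1 - (grid - 0.3) ** 2) - 0.01

    def test_same_seed_identical_trace(self):
        objective = lambda x: np.sin(5 * x)
        space = SearchSpace("x", 0.0, 1.0)
        r1 = bayes_opt(objective, space, n_iter=8, n_init=4, seed=5)
        r2 = bayes_opt(objective, space, n_iter=8, n_init=4, seed=5)
        assert r1.trace == r2.trace

    def test_incumbent_monotone_and_consistent(self):
        objective = lambda x: -(x - 0.7) ** 2
        result = bayes_opt(objective, SearchSpace("x", 0.0, 1.0),
                           n_iter=10, n_init=4, seed=1)
        curve = result.incumbent_curve()
        assert np.all(np.diff(curve) >= 0)
        assert result.best_y == curve[-1] == max(y for _, y in result.trace)

    def test_failed_evaluations_are_skipped(self):
        def objective(x):
            if x > 0.5:
                raise RuntimeError("boom")
            return x
        result = bayes_opt(objective, SearchSpace("x", 0.0, 1.0),
                           n_iter=5, n_init=5, seed=2)
        assert all(x <= 0.5 for x, _ in result.trace)

    def test_integer_space_rounds(self):
        seen = []
        objective = lambda k: seen.append(k) or -abs(k - 7)
        bayes_opt(objective, KNN_K_SPACE, n_iter=5, n_init=3, seed=3)
        assert all(float(k).is_integer() for k in seen)


class TestCVObjective:
    def make_separable(self, n_per_class=15, rng=None):
        """Classes along three different axes: separable in both the
        Euclidean (SVM) and angular (cosine k-NN) senses."""
        rng = rng or np.random.default_rng(0)
        X = rng.normal(size=(3 * n_per_class, 4))
        y = np.repeat(["AD", "HC", "FTD"], n_per_class)
        for j, cls in enumerate(("AD", "HC", "FTD")):
            X[y == cls, j] += 20.0
        return X, y

    def test_perfectly_informative_feature_gives_accuracy_one(self):
        X, y = self.make_separable()
        for family, h in (("svm", 1.0), ("knn", 3)):
            assert cv_objective(X, y, family, h, folds=5, seed=0) == 1.0

    def test_permuted_labels_near_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 5))
            y = np.repeat(["AD", "HC", "FTD"], 20)
            accs.append(cv_objective(X, y, "knn", 5, folds=5, seed=seed))
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.1)

    def test_exhaustive_per_fold_loop_oracle(self):
        """cv_objective equals a brute-force loop that walks the same
        stratified folds, refits standardisation and predicts each
        held-out row one at a time (15-row problem, max folds)."""
        from sklearn.model_selection import StratifiedKFold

        X, y = self.make_separable(n_per_class=5)
        X += np.random.default_rng(1).normal(scale=15.0, size=X.shape)
        folds, seed = 5, 0  # one row per class per fold: stratified LOO
        got = cv_objective(X, y, "knn", 1, folds=folds, seed=seed)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_accs = []
        for tr, te in skf.split(X, y):
            stats = standardize_fit(X[tr])
            Z_tr = standardize_apply(X[tr], stats)
            hits = []
            for i in te:
                Z_te = standardize_apply(X[[i]], stats)
                pred, _ = knn_predict(Z_tr, y[tr], Z_te, KNNConfig(k=1))
                hits.append(pred[0] == y[i])
            fold_accs.append(np.mean(hits))
        assert got == pytest.approx(np.mean(fold_accs), abs=1e-12)

    def test_class_smaller_than_folds_rejected(self):
        X = np.zeros((6, 2))
        y = np.array(["AD"] * 3 + ["HC"] * 3)
        with pytest.raises(ValueError):
            cv_objective(X, y, "svm", 1.0, folds=5)

    def test_resubstitution_at_least_cv(self):
        X, y = self.make_separable(n_per_class=10)
        X += np.random.default_rng(2).normal(scale=8.0, size=X.shape)
        resub = resubstitution_objective(X, y, "knn", 1)
        assert resub == 1.0  # k = 1 memorises the training set
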