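"""PLSDA core: NIPALS vs oracles, ROC, CV schemes, permutation null, VIP,
feature selection, combined score."""

import numpy as np
import pytest
from scipy.stats import kstest

import cytocode as cc
from cytocode.plsda import PLSDA, _folds

from conftest import PLANTED, krylov_pls_beta, make_planted_cohort, pairwise_auc


def random_problem(rng, n=50, p=6):
    X = rng.normal(size=(n, p))
    y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    rng.shuffle(y)
    return X, y


class TestFit:
    def test_beta_matches_krylov_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            X, y = random_problem(rng)
            m = PLSDA(n_components=2).fit(X, y)
            assert np.allclose(m.coef_, krylov_pls_beta(X, y, 2), atol=1e-8)

    def test_full_rank_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        X, y = random_problem(rng, n=20, p=3)
        m = PLSDA(n_components=3).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ols = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)[0]
        assert np.allclose(m.coef_, ols, atol=1e-8)

    def test_predictions_match_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, n=60, p=8)
        mine = PLSDA(n_components=2).fit(X, y).decision_function(X)
        ref = PLSRegression(n_components=2, scale=True).fit(X, y).predict(X).ravel()
        assert np.allclose(mine, ref, atol=1e-8)

    def test_perfect_separator_dominates(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(25), np.ones(25)]
        X = rng.normal(size=(50, 5))
        X[:, 2] = y * 2.0
        m = PLSDA(n_components=2).fit(X, y)
        assert np.argmax(np.abs(m.coef_)) == 2
        auc, _, _ = cc.roc_auc(m.decision_function(X), y)
        assert auc == 1.0

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X, y = random_problem(rng, n=40, p=7)
            m = PLSDA(n_components=3).fit(X, y)
            assert m.score_orthogonality() < 1e-8

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        X, y = random_problem(rng)
        perm = rng.permutation(X.shape[1])
        b1 = PLSDA(2).fit(X, y).coef_
        b2 = PLSDA(2).fit(X[:, perm], y).coef_
        assert np.allclose(b1[perm], b2, atol=1e-10)

    def test_autoscaled_fit_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(7)
        X, y = random_problem(rng)
        scales = rng.uniform(0.1, 10, X.shape[1])
        shifts = rng.normal(0, 5, X.shape[1])
        b1 = PLSDA(2, scale=True).fit(X, y).coef_
        b2 = PLSDA(2, scale=True).fit(X * scales + shifts, y).coef_
        assert np.allclose(b1, b2, atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            PLSDA(2).fit(np.random.default_rng(0).normal(size=(10, 3)),
                         np.zeros(10))

    def test_constant_feature_named_in_error(self):
        rng = np.random.default_rng(8)
        X, y = random_problem(rng)
        X[:, 4] = 3.3
        with pytest.raises(ValueError, match="column 4"):
            PLSDA(2).fit(X, y)


class TestPredict:
    def test_training_data_reproduces_fitted_values(self):
        rng = np.random.default_rng(9)
        X, y = random_problem(rng)
        m = PLSDA(2).fit(X, y)
        T, q = m.x_scores_, m.y_loadings_
        fitted = T @ q + m.intercept_
        assert np.allclose(m.decision_function(X), fitted, atol=1e-10)

    def test_mean_vector_scores_at_class_prior(self):
        rng = np.random.default_rng(10)
        X, y = random_problem(rng)
        m = PLSDA(2).fit(X, y)
        s = m.decision_function(X.mean(axis=0, keepdims=True))
        assert s[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_duplicate_event_identical_score(self):
        rng = np.random.default_rng(11)
        X, y = random_problem(rng)
        m = PLSDA(2).fit(X, y)
        s = m.decision_function(np.vstack([X[3], X[3]]))
        assert s[0] == s[1]

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        X, y = random_problem(rng)
        m = PLSDA(2).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            m.decision_function(X[:, :4])


class TestROC:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        # positives score 1 and 3: only (3 > 2) of the four pairs concords
        ([1, 2, 3, 4], [1, 0, 1, 0], 0.25),
        ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),
    ])
    def test_known_values(self, scores, labels, expected):
        auc, _, _ = cc.roc_auc(scores, labels)
        assert auc == pytest.approx(expected)

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(13)
        for n in (10, 57, 200):
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            auc, _, _ = cc.roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_sign_flip_mirrors_roc(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        a1, _, _ = cc.roc_auc(scores, labels)
        a2, _, _ = cc.roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cc.roc_auc([1, 2, 3], [1, 1, 1])

    def test_curve_endpoints(self):
        auc, fpr, tpr = cc.roc_auc([3, 1, 2, 4], [1, 0, 0, 1])
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0


class TestCrossValidation:
    def test_venetian_fold_definition(self):
        folds = _folds(20, 10, "venetian", np.random.default_rng(0))
        assert list(folds[0]) == [0, 10]
        assert list(folds[1]) == [1, 11]
        assert list(folds[9]) == [9, 19]

    def test_block_fold_boundaries(self):
        folds = _folds(100, 10, "block", np.random.default_rng(0))
        assert all(len(f) == 10 for f in folds)
        assert list(folds[3]) == list(range(30, 40))

    def test_folds_partition_events(self):
        for scheme in ("random", "venetian", "block"):
            folds = _folds(57, 10, scheme, np.random.default_rng(1))
            allidx = np.sort(np.concatenate(folds))
            assert np.array_equal(allidx, np.arange(57))

    def test_cv_auc_close_to_calibration_on_separable_cohort(self):
        """High-n separable data: pooled CV AUC tracks the calibration AUC
        (<= 0.02 apart) for every fold scheme."""
        diffs = []
        for seed in range(5):
            X, y, _, _ = make_planted_cohort(seed=seed, n_events=5000)
            m = PLSDA(2).fit(X, y)
            cal, _, _ = cc.roc_auc(m.decision_function(X), y)
            for scheme in ("random", "venetian", "block"):
                cv = cc.cross_validate(X, y, scheme=scheme, seed=seed)
                diffs.append(abs(cv["pooled_auc"] - cal))
        assert max(diffs) <= 0.02

    def test_single_class_fold_skipped_with_warning(self):
        X = np.random.default_rng(2).normal(size=(30, 4))
        y = np.r_[np.ones(3), np.zeros(27)]  # block folds can isolate class 1
        with pytest.warns(UserWarning, match="single-class"):
            res = cc.cross_validate(X, y, scheme="block", holdout=1 / 3)
        assert len(res["skipped"]) >= 1


class TestPermutation:
    def test_null_pvalues_uniform(self):
        """Labels independent of X: permutation p-values are U(0,1)
        (KS test per feature over 20 seeds, alpha=0.01)."""
        rng = np.random.default_rng(15)
        pvals = []
        for seed in range(20):
            X = rng.normal(size=(200, 6))
            y = np.r_[np.zeros(100), np.ones(100)]
            rng.shuffle(y)
            perm = cc.permutation_test_beta(X, y, B=500, seed=seed)
            pvals.append(perm.p_two_sided)
        pvals = np.concatenate(pvals)
        _, ks_p = kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_dominant_feature_reaches_floor(self):
        rng = np.random.default_rng(16)
        n = 2000
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        rng.shuffle(y)
        X = rng.normal(size=(n, 5))
        X[:, 1] += 2.0 * y  # d = 2 planted shift
        perm = cc.permutation_test_beta(X, y, B=999, seed=0)
        assert perm.p_two_sided[1] == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)
        r1 = cc.permutation_test_beta(X, y, B=200, seed=5)
        r2 = cc.permutation_test_beta(X, y, B=200, seed=5)
        assert np.array_equal(r1.null_beta, r2.null_beta)
        assert np.array_equal(r1.p_two_sided, r2.p_two_sided)

    def test_pvalues_bounded_away_from_zero(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        perm = cc.permutation_test_beta(X, y, B=100, seed=1)
        assert (perm.p_two_sided >= 1 / 101).all()
        assert (perm.p_two_sided <= 1.0).all()

    def test_small_B_rejected(self):
        with pytest.raises(ValueError, match="B"):
            cc.permutation_test_beta(np.zeros((10, 2)), np.zeros(10), B=50)


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            X = rng.normal(size=(40, 9))
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            v = cc.vip_scores(PLSDA(2).fit(X, y))
            assert (v ** 2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_single_lv_axis_aligned_weights(self):
        """One LV with weight (1, 0): VIP = (sqrt(2), 0) by the formula."""
        y = np.r_[np.zeros(20), np.ones(20)]
        X = np.column_stack([y * 2.0 + 1.0,
                             np.ones(40)])
        m = PLSDA(n_components=1, scale=False).fit(X, y)
        v = cc.vip_scores(m)
        assert np.allclose(v, [np.sqrt(2.0), 0.0], atol=1e-8)

    def test_unfitted_model_rejected(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            cc.vip_scores(PLSDA(2))


class TestSelection:
    def test_planted_features_recovered_by_both_selectors(self):
        hits = 0
        for seed in range(5):
            X, y, feat, _ = make_planted_cohort(seed=seed)
            m = PLSDA(2).fit(X, y)
            perm = cc.permutation_test_beta(X, y, B=1000, seed=seed)
            sel = cc.select_features(perm, cc.vip_scores(m), feat, k=4)
            if (set(sel.by_permutation) == PLANTED
                    and set(sel.by_vip) == PLANTED and sel.agreement):
                hits += 1
        assert hits >= 4

    def test_pure_noise_returns_both_sets_without_error(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(200, 8))
        y = rng.integers(0, 2, 200)
        perm = cc.permutation_test_beta(X, y, B=200, seed=0)
        m = PLSDA(2).fit(X, y)
        sel = cc.select_features(perm, cc.vip_scores(m),
                                 [f"f{i}" for i in range(8)], k=4)
        assert len(sel.by_permutation) == 4
        assert isinstance(sel.agreement, bool)

    def test_k_zero_and_k_too_large(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(50, 4))
        y = np.r_[np.zeros(25), np.ones(25)]
        perm = cc.permutation_test_beta(X, y, B=100, seed=0)
        m = PLSDA(2).fit(X, y)
        v = cc.vip_scores(m)
        sel = cc.select_features(perm, v, list("abcd"), k=0)
        assert sel.by_permutation == []
        with pytest.raises(ValueError):
            cc.select_features(perm, v, list("abcd"), k=5)

    def test_ties_broken_by_beta_magnitude(self):
        from cytocode.plsda import PermutationResult
        perm = PermutationResult(
            observed_beta=np.array([0.1, 0.9, 0.5]),
            null_beta=np.zeros((100, 3)),
            p_two_sided=np.array([0.01, 0.01, 0.01]),
            B=100, seed=0)
        sel = cc.select_features(perm, np.array([2.0, 0.1, 0.1]),
                                 ["a", "b", "c"], k=2)
        assert sel.by_permutation == ["b", "c"]


class TestCombinedScore:
    def test_single_feature_identity(self, planted_cohort):
        _, _, feat, ent = planted_cohort
        s = cc.combined_score(ent, ["p-P38"], [+1])
        assert np.array_equal(s, ent.column("p-P38"))

    def test_combination_beats_single_markers(self, planted_cohort):
        X, y, feat, ent = planted_cohort
        signs = {"p-P38": +1, "p-CREB": +1, "p-ERK": -1, "CK20": -1}
        s = cc.combined_score(ent, list(signs), list(signs.values()))
        comb, _, _ = cc.roc_auc(s, y)
        for f in signs:
            single, _, _ = cc.roc_auc(signs[f] * ent.column(f), y)
            assert comb >= single - 0.01

    def test_flipping_signs_mirrors_auc(self, planted_cohort):
        X, y, feat, ent = planted_cohort
        s = cc.combined_score(ent, ["p-P38", "p-ERK"], [+1, -1])
        s_flip = cc.combined_score(ent, ["p-P38", "p-ERK"], [-1, +1])
        a, _, _ = cc.roc_auc(s, y)
        b, _, _ = cc.roc_auc(s_flip, y)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_missing_feature_rejected(self, planted_cohort):
        _, _, _, ent = planted_cohort
        with pytest.raises(KeyError):
            cc.combined_score(ent, ["no-such-marker"], [+1])
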