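"""Classifiers, stratified folds, metric panels and ROC/AUC."""

import numpy as np
import pytest

from sweatvoc import (
    ConfusionMatrix,
    SweatvocError,
    confusion_and_metrics,
    cross_validate,
    fit_predict_knn,
    fit_predict_lda,
    fit_predict_linsvm,
    fit_predict_logreg,
    metrics_panel,
    roc_auc,
    stratified_kfold,
)

from .oracles import run_oracle


def _labels(n_co, n_crc):
    return np.array(["CO"] * n_co + ["CRC"] * n_crc, dtype=object)


class TestStratifiedKFold:
    def test_cohort_counts_force_balanced_folds(self):
        lab = _labels(34, 31)
        folds = stratified_kfold(lab, k=5, seed=0)
        for f in range(5):
            sel = folds == f
            assert sel.sum() == 13
            assert (lab[sel] == "CO").sum() in (6, 7)
            assert (lab[sel] == "CRC").sum() in (6, 7)

    def test_k_one_rejected(self):
        with pytest.raises(SweatvocError):
            stratified_kfold(_labels(5, 5), k=1)

    def test_small_class_rejected(self):
        with pytest.raises(SweatvocError, match="fewer than k"):
            stratified_kfold(_labels(20, 3), k=5)

    def test_seeds_differ_but_both_balanced(self):
        lab = _labels(20, 17)
        f1 = stratified_kfold(lab, k=5, seed=1)
        f2 = stratified_kfold(lab, k=5, seed=2)
        assert not np.array_equal(f1, f2)
        for folds in (f1, f2):
            for cls in ("CO", "CRC"):
                counts = [np.sum((folds == f) & (lab == cls)) for f in range(5)]
                assert max(counts) - min(counts) <= 1

    def test_deterministic_given_seed(self):
        lab = _labels(12, 11)
        np.testing.assert_array_equal(
            stratified_kfold(lab, k=5, seed=9), stratified_kfold(lab, k=5, seed=9)
        )


class TestKNN:
    def test_coincident_points_vote_their_class(self):
        train = np.zeros((6, 2))
        train[5] = [10, 10]
        lab = np.array(["CRC"] * 5 + ["CO"], dtype=object)
        preds, scores = fit_predict_knn(train, lab, np.zeros((1, 2)), k=5)
        assert preds[0] == "CRC" and scores[0] == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        train = rng.standard_normal((40, 3))
        lab = _labels(22, 18)[rng.permutation(40)]
        test = rng.standard_normal((15, 3))
        preds, _ = fit_predict_knn(train, lab, test, k=5)
        np.testing.assert_array_equal(preds, run_oracle("knn_bruteforce", train, lab, test, k=5))

    def test_tie_rules_are_deterministic(self):
        with pytest.warns(UserWarning, match="even k"):
            # equal votes, CRC neighbour closer → CRC
            train = np.array([[1.0], [-2.0]])
            preds, _ = fit_predict_knn(train, np.array(["CRC", "CO"], object), [[0.0]], k=2)
            assert preds[0] == "CRC"
        with pytest.warns(UserWarning, match="even k"):
            # equal votes, equal distances → negative class
            train = np.array([[1.0], [-1.0]])
            preds, _ = fit_predict_knn(train, np.array(["CRC", "CO"], object), [[0.0]], k=2)
            assert preds[0] == "CO"

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(SweatvocError):
            fit_predict_knn(np.zeros((3, 1)), _labels(2, 1), np.zeros((1, 1)), k=5)


class TestLDA:
    def test_separated_gaussians_classified_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((25, 3)) - 4, rng.standard_normal((25, 3)) + 4])
        lab = _labels(25, 25)
        preds, scores = fit_predict_lda(X, lab, X)
        assert (preds == lab).all()
        _, auc = roc_auc(lab, scores)
        assert auc == 1.0

    def test_direction_matches_hand_inverse_oracle(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + [2, 1]])
        lab = _labels(30, 30)
        test = rng.standard_normal((5, 2))
        _, scores = fit_predict_lda(X, lab, test, shrinkage_eps=0.0)
        mu0, mu1 = X[:30].mean(0), X[30:].mean(0)
        S = ((X[:30] - mu0).T @ (X[:30] - mu0) + (X[30:] - mu1).T @ (X[30:] - mu1)) / 58
        # 2x2 inverse by adjugate
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        w = Sinv @ (mu1 - mu0)
        b = -0.5 * (mu0 + mu1) @ w
        np.testing.assert_allclose(scores, test @ w + b, atol=1e-8)

    def test_identical_means_give_chance_auc(self, rng):
        X = rng.standard_normal((100, 4))
        lab = _labels(50, 50)
        res = cross_validate(X, lab, classifier="lda", k_folds=5, seed=0)
        assert 0.3 < res.auc < 0.7

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        X = np.vstack([rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 1])
        lab = _labels(20, 20)
        test = rng.standard_normal((30, 3))
        preds, _ = fit_predict_lda(X, lab, test, shrinkage_eps=0.0)
        ref = sk.LinearDiscriminantAnalysis(solver="svd").fit(X, (lab == "CRC").astype(int))
        np.testing.assert_array_equal((preds == "CRC").astype(int), ref.predict(test))


class TestLogisticRegression:
    def test_separable_data_has_finite_weights_and_zero_errors(self, rng):
        X = np.vstack([rng.standard_normal((15, 2)) - 3, rng.standard_normal((15, 2)) + 3])
        lab = _labels(15, 15)
        preds, scores = fit_predict_logreg(X, lab, X, l2=1.0)
        assert (preds == lab).all()
        assert np.all(np.isfinite(scores))

    def test_matches_sklearn_penalized_optimum(self, rng):
        linear_model = pytest.importorskip("sklearn.linear_model")
        X = rng.standard_normal((20, 2))
        lab = _labels(10, 10)
        n, l2 = 20, 1.0
        ref = linear_model.LogisticRegression(C=1.0 / (n * l2), tol=1e-10, max_iter=5000).fit(
            X, (lab == "CRC").astype(int)
        )
        test = np.eye(2)
        _, scores = fit_predict_logreg(X, lab, test, l2=l2, tol=1e-10)
        ref_scores = test @ ref.coef_[0] + ref.intercept_[0]
        np.testing.assert_allclose(scores, ref_scores, atol=1e-4)

    def test_null_features_give_chance_level_cv(self, rng):
        X = rng.standard_normal((80, 3))
        lab = _labels(40, 40)
        res = cross_validate(X, lab, classifier="lr", k_folds=5, seed=3)
        assert 30.0 < res.accuracy < 70.0


class TestLinearSVM:
    def test_separable_data_classified_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((15, 2)) - 3, rng.standard_normal((15, 2)) + 3])
        lab = _labels(15, 15)
        preds, _ = fit_predict_linsvm(X, lab, X)
        assert (preds == lab).all()

    def test_primal_objective_matches_sklearn(self, rng):
        svm_mod = pytest.importorskip("sklearn.svm")
        X = rng.standard_normal((30, 3))
        lab = _labels(15, 15)
        y = 2 * (lab == "CRC").astype(float) - 1
        C = 1.0

        def primal(w):
            margins = 1 - y * (np.hstack([X, np.ones((30, 1))]) @ w)
            return 0.5 * w @ w + C * np.maximum(margins, 0).sum()

        _, scores = fit_predict_linsvm(X, lab, np.eye(3), C=C, tol=1e-6, max_iter=20000)
        # recover our w from scores on the identity test matrix + origin
        _, s0 = fit_predict_linsvm(X, lab, np.zeros((1, 3)), C=C, tol=1e-6, max_iter=20000)
        w_ours = np.r_[scores - s0[0], s0[0]]
        ref = svm_mod.LinearSVC(
            C=C, loss="hinge", tol=1e-8, max_iter=200000, intercept_scaling=1.0
        ).fit(X, y)
        w_ref = np.r_[ref.coef_[0], ref.intercept_[0]]
        assert primal(w_ours) <= primal(w_ref) * (1 + 1e-3)


class TestMetrics:
    def test_reference_gcms_counts_reproduce_panel(self, reference_counts):
        c = reference_counts["gcms_knn"]["counts"]
        panel = metrics_panel(ConfusionMatrix(**c)).to_frame(decimals=1)
        exp = reference_counts["gcms_knn"]["expected"]
        assert panel.loc["accuracy", "CO"] == exp["accuracy"]
        for cls in ("CO", "CRC"):
            for metric in ("sensitivity", "specificity", "precision", "f1"):
                assert panel.loc[metric, cls] == exp[cls][metric], (cls, metric)

    def test_panel_matches_counts_oracle(self, rng):
        tn, fp, fn, tp = rng.integers(1, 50, size=4)
        panel = metrics_panel(ConfusionMatrix(int(tn), int(fp), int(fn), int(tp)))
        oracle = run_oracle("metrics_from_counts", int(tn), int(fp), int(fn), int(tp))
        for cls in ("CO", "CRC"):
            for k, v in oracle[cls].items():
                assert panel.per_class[cls][k] == pytest.approx(v)

    def test_perfect_predictions_give_all_100(self):
        panel = metrics_panel(ConfusionMatrix(10, 0, 0, 12))
        for cls in ("CO", "CRC"):
            assert all(v == 100.0 for v in panel.per_class[cls].values())

    def test_label_swap_symmetry(self, rng):
        truth = _labels(9, 11)[rng.permutation(20)]
        preds = truth.copy()
        flip = rng.random(20) < 0.3
        preds[flip] = np.where(preds[flip] == "CO", "CRC", "CO")
        _, panel = confusion_and_metrics(truth, preds)
        swap = {"CO": "CRC", "CRC": "CO"}
        truth_s = np.array([swap[t] for t in truth], object)
        preds_s = np.array([swap[p] for p in preds], object)
        _, panel_s = confusion_and_metrics(truth_s, preds_s)
        for cls in ("CO", "CRC"):
            for metric in ("sensitivity", "specificity", "precision", "f1"):
                assert panel.per_class[cls][metric] == pytest.approx(
                    panel_s.per_class[swap[cls]][metric]
                )

    def test_unseen_label_rejected(self):
        with pytest.raises(SweatvocError):
            confusion_and_metrics(["CO", "XX"], ["CO", "CO"])


class TestROC:
    def test_perfect_ranking_gives_auc_one(self):
        truth = _labels(3, 3)
        _, auc = roc_auc(truth, [0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        truth = _labels(4, 4)
        _, auc = roc_auc(truth, np.zeros(8))
        assert auc == 0.5

    def test_ties_match_pair_counting_oracle_exactly(self, rng):
        truth = _labels(5, 7)[rng.permutation(12)]
        scores = rng.integers(0, 4, size=12).astype(float)  # heavy ties
        _, auc = roc_auc(truth, scores)
        oracle = run_oracle("auc_pairs", (truth == "CRC").astype(int), scores)
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_score_transforms(self, rng):
        truth = _labels(10, 10)[rng.permutation(20)]
        scores = rng.standard_normal(20)
        _, a1 = roc_auc(truth, scores)
        _, a2 = roc_auc(truth, np.exp(scores))
        _, a3 = roc_auc(truth, 5 * scores - 3)
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_single_class_rejected(self):
        with pytest.raises(SweatvocError):
            roc_auc(["CO", "CO"], [0.1, 0.2])


class TestCrossValidate:
    def test_every_sample_predicted_exactly_once(self, rng):
        X = rng.standard_normal((37, 3))
        lab = _labels(19, 18)
        res = cross_validate(X, lab, classifier="knn", k_folds=5, seed=2)
        assert res.predictions.shape == (37,)
        assert not any(p is None for p in res.predictions)
        assert res.confusion.total == 37

    def test_pooled_metrics_equal_concatenated_fold_metrics(self, rng):
        X = rng.standard_normal((30, 2))
        X[15:] += 1.0
        lab = _labels(15, 15)
        res = cross_validate(X, lab, classifier="lda", k_folds=5, seed=4)
        cm2, panel2 = confusion_and_metrics(lab, res.predictions)
        assert (cm2.tn, cm2.fp, cm2.fn, cm2.tp) == (
            res.confusion.tn, res.confusion.fp, res.confusion.fn, res.confusion.tp
        )
        assert panel2.accuracy == res.metrics.accuracy
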