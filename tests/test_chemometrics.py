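"""PCA, PLS-DA/VIP, OSC and PERMANOVA against independent oracles."""

import numpy as np
import pytest

from sweatvoc import (
    FeatureMatrix,
    SweatvocError,
    fit_pca,
    fit_plsda,
    osc_correct,
    permanova,
    vip_scores,
)

from .oracles import run_oracle


def _fm(X, labels):
    X = np.asarray(X, float)
    return FeatureMatrix.from_arrays(X, labels, [f"f{j}" for j in range(X.shape[1])])


def _two_group_labels(n):
    return ["CO"] * (n // 2) + ["CRC"] * (n - n // 2)


class TestPCA:
    def test_collinear_points_have_single_component(self, rng):
        x = rng.uniform(-1, 1, 30)
        model = fit_pca(np.column_stack([x, x]), n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        assert model.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.standard_normal((12, 5))
        model = fit_pca(X, n_components=5)
        recon = model.scores @ model.loadings.T
        np.testing.assert_allclose(recon, X - model.center, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 6))
        model = fit_pca(X, n_components=6)
        evals, evecs = run_oracle("eigen_pca", X)
        sv2 = (model.scores**2).sum(axis=0) / (X.shape[0] - 1)
        np.testing.assert_allclose(sv2, evals, atol=1e-8)
        for a in range(6):
            cos = abs(model.loadings[:, a] @ evecs[:, a])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_scores_are_uncorrelated(self, rng):
        model = fit_pca(rng.standard_normal((25, 7)), n_components=5)
        cov = np.cov(model.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((15, 6))
        model = fit_pca(X, n_components=3)
        ref = sk.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(model.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10)
        for a in range(3):
            assert abs(model.loadings[:, a] @ ref.components_[a]) == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(SweatvocError):
            fit_pca(np.ones((5, 3)), n_components=2)


class TestPLSDA:
    def test_single_feature_equal_to_y_explains_everything(self):
        y = np.array([0.0] * 6 + [1.0] * 6)
        m = _fm(y[:, None], _two_group_labels(12))
        model = fit_plsda(m, n_lv=1)
        assert model.explained_y_ratio[0] == pytest.approx(1.0)

    def test_x_orthogonal_to_y_explains_nothing(self, rng):
        y = np.array([0.0] * 10 + [1.0] * 10)
        yc = y - y.mean()
        X = rng.standard_normal((20, 4))
        X -= np.outer(yc, yc @ X / (yc @ yc))  # project out the class direction
        model = fit_plsda(_fm(X, _two_group_labels(20)), n_lv=1)
        assert abs(model.y_loadings[0]) < 1e-8
        assert model.explained_y_ratio[0] == pytest.approx(0.0, abs=1e-12)

    def test_first_weight_is_dominant_eigenvector_of_xtyyx(self, rng):
        X = rng.standard_normal((12, 4))
        labels = _two_group_labels(12)
        model = fit_plsda(_fm(X, labels), n_lv=1)
        y = (np.asarray(labels) == "CRC").astype(float)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        M = np.outer(Xc.T @ yc, yc @ Xc)
        evals, evecs = np.linalg.eig(M)
        v = np.real(evecs[:, np.argmax(np.real(evals))])
        assert abs(model.weights[:, 0] @ (v / np.linalg.norm(v))) == pytest.approx(1.0, abs=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.standard_normal((20, 8))
        model = fit_plsda(_fm(X, _two_group_labels(20)), n_lv=4)
        T = model.scores
        for a in range(4):
            for b in range(a + 1, 4):
                bound = 1e-8 * np.linalg.norm(T[:, a]) * np.linalg.norm(T[:, b])
                assert abs(T[:, a] @ T[:, b]) < bound + 1e-12

    def test_transform_reproduces_training_scores(self, rng):
        X = rng.standard_normal((16, 5))
        m = _fm(X, _two_group_labels(16))
        model = fit_plsda(m, n_lv=3)
        np.testing.assert_allclose(model.transform(m), model.scores, atol=1e-8)

    def test_full_rank_pls_matches_least_squares(self, rng):
        X = rng.standard_normal((20, 4))
        labels = _two_group_labels(20)
        model = fit_plsda(_fm(X, labels), n_lv=4)
        y = (np.asarray(labels) == "CRC").astype(float)
        Xc = X - X.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(
            model.predict_value(_fm(X, labels)), y.mean() + Xc @ beta, atol=1e-6
        )

    def test_matches_sklearn_nipals(self, rng):
        cross = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((18, 6))
        labels = _two_group_labels(18)
        y = (np.asarray(labels) == "CRC").astype(float)
        model = fit_plsda(_fm(X, labels), n_lv=3)
        ref = cross.PLSRegression(n_components=3, scale=False).fit(X, y)
        for a in range(3):
            cos = abs(model.scores[:, a] @ ref.x_scores_[:, a]) / (
                np.linalg.norm(model.scores[:, a]) * np.linalg.norm(ref.x_scores_[:, a])
            )
            assert cos == pytest.approx(1.0, abs=1e-8)


class TestVIP:
    def test_equal_weights_give_unit_vips(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        x = y - 0.5
        m = _fm(np.column_stack([x, x]), ["CO", "CO", "CRC", "CRC"])
        model = fit_plsda(m, n_lv=1)
        np.testing.assert_allclose(vip_scores(model), [1.0, 1.0], atol=1e-10)

    def test_direct_formula_on_known_weights(self):
        # one LV with w = (0.6, 0.8) → VIP = (sqrt(0.72), sqrt(1.28))
        y = np.array([0.0] * 8 + [1.0] * 8)
        yc = y - 0.5
        X = np.column_stack([0.6 * yc, 0.8 * yc])
        model = fit_plsda(_fm(X, _two_group_labels(16)), n_lv=1)
        np.testing.assert_allclose(model.weights[:, 0], [0.6, 0.8], atol=1e-10)
        np.testing.assert_allclose(vip_scores(model), np.sqrt([0.72, 1.28]), atol=1e-8)

    def test_sum_of_squares_equals_feature_count(self, rng):
        X = rng.standard_normal((30, 11))
        model = fit_plsda(_fm(X, _two_group_labels(30)), n_lv=3)
        v = vip_scores(model)
        assert np.sum(v**2) == pytest.approx(11.0, rel=1e-6)

    def test_ordering_invariant_to_prescaling_before_autoscale(self, rng):
        from sweatvoc import Normalizer

        X = rng.standard_normal((30, 6)) + np.linspace(0, 2, 6)
        labels = _two_group_labels(30)
        X[15:, 2] += 1.5
        scaled = X * np.array([1, 100, 0.01, 5, 1, 10.0])
        v1 = vip_scores(fit_plsda(Normalizer("autoscale").fit_transform(_fm(X, labels)), n_lv=2))
        v2 = vip_scores(fit_plsda(Normalizer("autoscale").fit_transform(_fm(scaled, labels)), n_lv=2))
        assert list(np.argsort(v1)) == list(np.argsort(v2))


class TestOSC:
    def test_zero_components_is_identity(self, rng):
        X = rng.standard_normal((10, 4))
        m = _fm(X, _two_group_labels(10))
        corrected, model = osc_correct(m, n_osc=0)
        np.testing.assert_array_equal(corrected.X, X)
        assert model.weights == []

    def test_removed_scores_orthogonal_to_class(self, rng):
        X = rng.standard_normal((30, 8))
        labels = _two_group_labels(30)
        y = (np.asarray(labels) == "CRC").astype(float)
        _, model = osc_correct(_fm(X, labels), n_osc=2)
        for t in model.scores:
            assert abs(np.corrcoef(t, y - y.mean())[0, 1]) < 1e-6

    def test_no_orthogonal_structure_leaves_x_unchanged(self):
        # X built entirely from the class direction: nothing to remove
        y = np.array([0.0] * 10 + [1.0] * 10)
        yc = y - y.mean()
        load = np.array([1.0, -2.0, 0.5])
        X = np.outer(yc, load)
        corrected, _ = osc_correct(_fm(X, _two_group_labels(20)), n_osc=1)
        rel = np.linalg.norm(corrected.X - X) / max(np.linalg.norm(X), 1e-30)
        assert rel < 1e-6

    def test_heldout_transform_uses_only_stored_weights(self, rng):
        X = rng.standard_normal((40, 6)) + np.outer(rng.standard_normal(40), np.ones(6)) * 3
        labels = _two_group_labels(40)
        m = _fm(X, labels)
        train = m.iloc_samples(range(30))
        test = m.iloc_samples(range(30, 40))
        _, model = osc_correct(train, n_osc=1)
        out1 = model.transform(test)
        relabeled = FeatureMatrix(test.values, test.labels.map({"CO": "CRC", "CRC": "CO"}))
        np.testing.assert_array_equal(model.transform(relabeled), out1)

    def test_removes_planted_shared_nuisance_direction(self, rng):
        nuisance = rng.standard_normal(50)
        X = rng.standard_normal((50, 5)) * 0.1 + np.outer(nuisance, np.linspace(1, 2, 5))
        corrected, model = osc_correct(_fm(X, _two_group_labels(50)), n_osc=1)
        t = model.scores[0]
        assert abs(np.corrcoef(t, nuisance)[0, 1]) > 0.99


class TestPermanova:
    def test_identical_groups_not_significant(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        X = np.vstack([pts, pts])
        res = permanova(_fm(X, ["CO"] * 4 + ["CRC"] * 4), n_perm=199, seed=1)
        assert res.p_value > 0.5

    def test_matches_full_enumeration_on_three_plus_three(self, rng):
        X = rng.standard_normal((6, 3))
        labels = ["CO"] * 3 + ["CRC"] * 3
        f_oracle, p_oracle = run_oracle("permanova_enumeration", X, np.asarray(labels))
        res = permanova(_fm(X, labels), n_perm=9999, seed=3)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        # permutation p converges to the enumeration value
        assert res.p_value == pytest.approx(p_oracle, abs=0.02)

    def test_f_statistic_matches_scikit_bio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix
        from scipy.spatial.distance import pdist, squareform

        X = rng.standard_normal((20, 4))
        X[10:] += 0.8
        labels = ["CO"] * 10 + ["CRC"] * 10
        res = permanova(_fm(X, labels), n_perm=99, seed=0)
        dm = DistanceMatrix(squareform(pdist(X)))
        ref = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert res.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-8)

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 400
        for _ in range(reps):
            X = rng.standard_normal((16, 3))
            labels = ["CO"] * 8 + ["CRC"] * 8
            res = permanova(_fm(X, labels), n_perm=99, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_tiny_group_rejected(self):
        with pytest.raises(SweatvocError):
            permanova(_fm(np.eye(3), ["CO", "CO", "CRC"]), n_perm=9)
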