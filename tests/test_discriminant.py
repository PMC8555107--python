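import numpy as np
import pandas as pd
import pytest

from peptidome_dx.discriminant import (
    LEAVE_ONE_OUT,
    MONTE_CARLO,
    PLSDAModel,
    cross_validate,
    fit_plsda,
    pca_variance,
    predict_plsda,
    select_discriminant,
    vip_scores,
)


def _labels(n_high, n_low):
    return np.array(["High"] * n_high + ["Low"] * n_low)


def _separable(rng, n=12, p=5, gap=11.0, noise=0.2):
    X = rng.normal(0, noise, size=(2 * n, p))
    X[:n] += gap
    return pd.DataFrame(X, index=[f"w{i}" for i in range(2 * n)]), _labels(n, n)


class TestFit:
    def test_single_separating_feature_orders_scores_by_class(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": np.r_[np.full(6, 5.0), np.zeros(6)] + rng.normal(0, 0.1, 12)})
        y = _labels(6, 6)
        model = fit_plsda(X, y, n_components=1)
        t1 = model.scores[:, 0]
        assert (t1[:6].min() > t1[6:].max()) or (t1[:6].max() < t1[6:].min())

    def test_scores_orthogonal_and_weights_unit_norm(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        model = fit_plsda(X, _labels(10, 10), n_components=3)
        T = model.scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8
        np.testing.assert_allclose(np.linalg.norm(model.weights, axis=1), 1.0)

    def test_first_weight_is_dominant_eigvec_of_cross_covariance(self):
        # For a single response the NIPALS first weight is X'y normalized,
        # the leading eigenvector of X' y y' X.
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(16, 6)))
        y = _labels(8, 8)
        model = fit_plsda(X, y, n_components=1)
        Xs = (X - X.mean()) / X.std(ddof=1)
        yc = (y == "Low").astype(float)
        yc -= yc.mean()
        ref = Xs.to_numpy().T @ yc
        ref /= np.linalg.norm(ref)
        assert np.abs(model.weights[0] @ ref) == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_predictions(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X, y = _separable(rng, n=8, p=6, gap=2.0, noise=1.0)
        model = fit_plsda(X, y, n_components=2)
        ours = predict_plsda(model, X)["y_pred"].to_numpy()
        y01 = (np.asarray(y) == model.classes[1]).astype(float)
        Xs = (X - X.mean()) / X.std(ddof=1)
        ref = PLSRegression(n_components=2, scale=False)
        ref.fit(Xs.to_numpy(), y01 - y01.mean())
        ref_pred = ref.predict(Xs.to_numpy()).ravel() + y01.mean()
        np.testing.assert_allclose(ours, ref_pred, atol=1e-8)

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_plsda(X, _labels(5, 5))
        assert model.feature_names == ["a"]

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(5).normal(size=(6, 3)))
        with pytest.raises(ValueError):
            fit_plsda(X, np.array(["High"] * 6))


class TestVIP:
    def test_closed_form_two_features(self):
        model = PLSDAModel(
            classes=("High", "Low"),
            feature_names=["a", "b"],
            x_mean=np.zeros(2),
            x_scale=np.ones(2),
            y_mean=0.5,
            weights=np.array([[0.8, 0.6]]),
            loadings=np.array([[0.8, 0.6]]),
            scores=np.zeros((4, 1)),
            y_loadings=np.array([1.0]),
            ssy_explained=np.array([1.0]),
        )
        vip = vip_scores(model)
        assert vip["a"] == pytest.approx(1.1314, abs=1e-4)
        assert vip["b"] == pytest.approx(0.8485, abs=1e-4)

    def test_equal_weights_give_unit_vip(self):
        p = 4
        model = PLSDAModel(
            classes=("High", "Low"),
            feature_names=list("abcd"),
            x_mean=np.zeros(p),
            x_scale=np.ones(p),
            y_mean=0.5,
            weights=np.full((1, p), 1 / np.sqrt(p)),
            loadings=np.full((1, p), 1 / np.sqrt(p)),
            scores=np.zeros((4, 1)),
            y_loadings=np.array([1.0]),
            ssy_explained=np.array([2.0]),
        )
        np.testing.assert_allclose(vip_scores(model), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_squared_vip_normalization(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(18, 12)))
        model = fit_plsda(X, _labels(9, 9), n_components=3)
        vip = vip_scores(model)
        assert float((vip**2).sum()) == pytest.approx(len(vip), rel=1e-9)

    def test_duplicated_features_share_vip(self):
        rng = np.random.default_rng(6)
        col = rng.normal(size=14)
        X = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=14)})
        model = fit_plsda(X, _labels(7, 7))
        vip = vip_scores(model)
        assert vip["a"] == pytest.approx(vip["b"], rel=1e-9)

    def test_selection_cutoff_and_top_k(self):
        vips = pd.Series({"a": 1.6, "b": 0.4, "c": 1.2, "d": 1.0})
        assert select_discriminant(vips) == ["a", "c", "d"]
        assert select_discriminant(vips, top_k=2) == ["a", "c"]
        assert select_discriminant(pd.Series({"a": 0.2}), cutoff=1.0) == []


class TestCrossValidation:
    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(7)
        X, y = _separable(rng)
        report = cross_validate(X, y, scheme=MONTE_CARLO, n_repeats=30, seed=1)
        assert report.accuracy == 1.0
        assert report.q2 > 0.99
        assert report.skipped_folds == 0
        probs = report.class_probability
        low = probs[np.asarray(y) == "Low"].dropna()
        high = probs[np.asarray(y) == "High"].dropna()
        assert low.min() > 0.9 and high.max() < 0.1  # P(class "Low")

    def test_leave_one_out_evaluates_each_worker_once(self):
        rng = np.random.default_rng(8)
        X, y = _separable(rng, n=6)
        report = cross_validate(X, y, scheme=LEAVE_ONE_OUT)
        assert report.n_repeats == 12
        assert report.n_evaluations.eq(1).all()

    def test_permuted_labels_destroy_prediction(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(24, 10)))
        accs, q2s = [], []
        for i in range(20):
            y = rng.permutation(_labels(12, 12))
            rep = cross_validate(X, y, n_repeats=10, seed=i)
            accs.append(rep.accuracy)
            q2s.append(rep.q2)
        assert abs(np.mean(accs) - 0.5) < 0.15
        assert np.mean(q2s) < 0.0

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(10)
        X, y = _separable(rng, noise=1.0, gap=1.0)
        a = cross_validate(X, y, n_repeats=15, seed=4)
        b = cross_validate(X, y, n_repeats=15, seed=4)
        assert a.q2 == b.q2 and a.accuracy == b.accuracy


class TestPCA:
    def test_diagonal_covariance_fractions(self):
        # Two uncorrelated features with variances 9 and 1 -> (0.9, 0.1).
        n = 40
        z = np.linspace(-1, 1, n)
        z = (z - z.mean()) / z.std(ddof=0)
        w = np.cos(np.pi * np.arange(n))  # orthogonal to z and centered
        w = (w - w.mean()) / w.std(ddof=0)
        w -= z * (z @ w) / (z @ z)
        X = pd.DataFrame({"a": 3.0 * z, "b": w / np.std(w)})
        frac = pca_variance(X).explained_fraction
        np.testing.assert_allclose(frac, [0.9, 0.1], atol=1e-9)

    def test_fractions_sum_to_one_and_rotation_invariant(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 6))
        res = pca_variance(pd.DataFrame(X))
        assert res.explained_fraction.sum() == pytest.approx(1.0)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        rotated = pca_variance(pd.DataFrame(X @ q))
        np.testing.assert_allclose(
            rotated.explained_fraction, res.explained_fraction, atol=1e-9
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_variance(pd.DataFrame(np.ones((5, 3))))
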