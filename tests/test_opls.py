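import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from polarscreen.opls import (
    OplsModel,
    _apply_scaler,
    _dummy,
    _fit_scaler,
    cross_validated_q2,
    fit_opls_da,
    s_plot,
    select_common_features,
    splot_frame,
)

from oracles import splot_oracle


def _two_class_data(rng, n_per=10, p=30, shift=4.0, noise=1.0):
    X = rng.normal(0, noise, (2 * n_per, p))
    X[n_per:, : p // 3] += shift  # class-correlated block
    classes = np.array(["a"] * n_per + ["b"] * n_per)
    return X, classes


class TestPlsLimit:
    def test_zero_orthogonal_matches_sklearn_pls(self):
        """With n_orthogonal=0 on pre-scaled data, the predictive scores
        and coefficients coincide with sklearn's NIPALS PLS regression."""
        rng = np.random.default_rng(0)
        for trial in range(50):
            n, p, k = 12, 8, 2
            X = rng.normal(size=(n, p))
            classes = np.array(["a", "b", "c"])[rng.integers(0, 3, n)]
            if len(set(classes)) < 2:
                continue
            Y, _ = _dummy(classes)
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            model = fit_opls_da(Z, classes, n_predictive=2, n_orthogonal=0,
                                scaling="center")
            # sklearn's tol is on the squared weight-difference norm; tighten
            # it so the oracle itself is converged well past 1e-8
            ref = PLSRegression(n_components=2, scale=False, tol=1e-28,
                                max_iter=50000).fit(Z, Y - Y.mean(0))
            for a in range(2):
                t_ours, t_ref = model.scores[:, a], ref.x_scores_[:, a]
                sign = np.sign(t_ours @ t_ref) or 1.0
                # sklearn normalizes scores differently; compare directions
                np.testing.assert_allclose(
                    t_ours / np.linalg.norm(t_ours),
                    sign * t_ref / np.linalg.norm(t_ref), atol=1e-8)
            np.testing.assert_allclose(model.coef, ref.coef_.T, atol=1e-8)

    def test_exact_low_rank_r2x_one(self):
        """A rank-1 X built from the class dummy is explained exactly."""
        rng = np.random.default_rng(1)
        classes = np.array(["a"] * 6 + ["b"] * 6)
        y = np.where(classes == "a", 1.0, -1.0)
        X = np.outer(y, rng.normal(size=10))
        model = fit_opls_da(X, classes, n_predictive=1, n_orthogonal=0,
                            scaling="center")
        assert model.r2x_cum == pytest.approx(1.0, abs=1e-10)
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-10)


class TestOrthogonality:
    def test_scores_orth_perpendicular_to_predictive_and_y(self):
        rng = np.random.default_rng(2)
        X, classes = _two_class_data(rng)
        # add structured within-class variation so an orthogonal component exists
        X += np.outer(rng.normal(0, 3, len(classes)), rng.normal(size=X.shape[1]))
        model = fit_opls_da(X, classes, n_orthogonal=1)
        t_o = model.scores_orth[:, 0]
        t1 = model.scores[:, 0]
        Y, _ = _dummy(classes)
        Yc = Y - Y.mean(0)
        assert abs(t_o @ t1) / (np.linalg.norm(t_o) * np.linalg.norm(t1)) < 1e-8
        for j in range(Yc.shape[1]):
            denom = np.linalg.norm(t_o) * (np.linalg.norm(Yc[:, j]) or 1.0)
            assert abs(t_o @ Yc[:, j]) / denom < 1e-8

    def test_separated_classes_scores_do_not_overlap(self):
        rng = np.random.default_rng(3)
        X, classes = _two_class_data(rng, shift=6.0, noise=0.5)
        model = fit_opls_da(X, classes)
        t1 = model.scores[:, 0]
        assert max(t1[classes == "a"]) < min(t1[classes == "b"]) or \
            max(t1[classes == "b"]) < min(t1[classes == "a"])

    def test_orthogonal_filter_improves_r2y_vs_pls_on_structured_noise(self):
        rng = np.random.default_rng(4)
        X, classes = _two_class_data(rng, shift=2.0)
        X += np.outer(rng.normal(0, 5, len(classes)), rng.normal(size=X.shape[1]))
        pls = fit_opls_da(X, classes, n_predictive=1, n_orthogonal=0)
        opls = fit_opls_da(X, classes, n_predictive=1, n_orthogonal=1)
        assert opls.r2y_cum >= pls.r2y_cum - 1e-10


class TestQ2:
    def test_null_data_q2_small(self):
        """Random class labels on pure noise: Q2 stays near or below 0."""
        rng = np.random.default_rng(5)
        vals = []
        for seed in range(20):
            X = rng.normal(size=(16, 25))
            classes = np.array(["a", "b"] * 8)
            vals.append(cross_validated_q2(X, classes, folds=4, seed=seed))
        assert np.mean(vals) <= 0.1

    def test_separated_classes_q2_high(self):
        rng = np.random.default_rng(6)
        X, classes = _two_class_data(rng, n_per=12, shift=6.0, noise=0.5)
        q2 = cross_validated_q2(X, classes, folds=4)
        assert q2 >= 0.8

    def test_q2_not_above_r2y(self):
        rng = np.random.default_rng(7)
        X, classes = _two_class_data(rng, n_per=12, shift=3.0)
        model = fit_opls_da(X, classes)
        q2 = cross_validated_q2(X, classes, folds=4)
        assert q2 <= model.r2y_cum + 1e-10

    def test_fold_reduction_warns(self):
        rng = np.random.default_rng(8)
        X, classes = _two_class_data(rng, n_per=3)
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validated_q2(X, classes, folds=7)

    def test_invalid_folds(self):
        rng = np.random.default_rng(9)
        X, classes = _two_class_data(rng, n_per=4)
        with pytest.raises(ValueError):
            cross_validated_q2(X, classes, folds=1)


class TestSPlot:
    def test_perfectly_correlated_feature_pcorr_one(self):
        """When every column is a multiple of the class contrast, t1 is
        proportional to it and every p(corr) is exactly +/-1."""
        classes = np.array(["a"] * 8 + ["b"] * 8)
        y = np.where(classes == "a", 1.0, -1.0)
        X = np.outer(y, [2.0, -1.0, 0.5, 3.0, -0.25])
        model = fit_opls_da(X, classes, n_orthogonal=0, scaling="center")
        pts = s_plot(model)
        for p in pts:
            assert abs(p.pcorr1) == pytest.approx(1.0, abs=1e-8)

    def test_uncorrelated_feature_near_zero(self):
        rng = np.random.default_rng(11)
        classes = np.array(["a"] * 50 + ["b"] * 50)
        y = np.where(classes == "a", 1.0, -1.0)
        X = np.column_stack([y, rng.normal(size=100)])
        model = fit_opls_da(X, classes, n_orthogonal=0, scaling="center")
        pts = s_plot(model)
        assert abs(pts[1].pcorr1) < 0.3

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(12)
        X, classes = _two_class_data(rng)
        model = fit_opls_da(X, classes)
        pts = s_plot(model)
        p1_o, pcorr_o = splot_oracle(model.scaled_x, model.scores[:, 0])
        np.testing.assert_allclose([p.p1 for p in pts], p1_o, atol=1e-10)
        np.testing.assert_allclose([p.pcorr1 for p in pts], pcorr_o, atol=1e-10)

    def test_zero_variance_flagged_not_nan(self):
        rng = np.random.default_rng(13)
        classes = np.array(["a"] * 6 + ["b"] * 6)
        X = rng.normal(size=(12, 3))
        X[:, 2] = 7.0
        model = fit_opls_da(X, classes, scaling="center")
        pts = s_plot(model)
        assert pts[2].zero_variance and pts[2].pcorr1 == 0.0

    def test_select_common_features_threshold_and_sorting(self):
        from polarscreen.opls import SPlotPoint
        pts = [SPlotPoint("hi", 1.0, 0.9), SPlotPoint("lo", 0.1, 0.05),
               SPlotPoint("mid", 0.2, -0.08)]
        sel = select_common_features(pts, pcorr_max=0.1)
        assert [p.feature for p in sel] == ["lo", "mid"]

    def test_select_common_features_class_balance(self):
        from polarscreen.opls import SPlotPoint
        pts = [SPlotPoint("x", 0.1, 0.05), SPlotPoint("y", 0.1, 0.02)]
        a = [SPlotPoint("x", 0, 0.04), SPlotPoint("y", 0, 0.30)]
        b = [SPlotPoint("x", 0, 0.06), SPlotPoint("y", 0, -0.30)]
        sel = select_common_features(pts, pcorr_max=0.1, balance_tol=0.05,
                                     class_splots=(a, b))
        assert [p.feature for p in sel] == ["x"]

    def test_splot_frame_columns(self):
        from polarscreen.opls import SPlotPoint
        df = splot_frame([SPlotPoint("f", 0.5, 0.4)])
        assert list(df.columns) == ["feature", "p1", "pcorr1", "zero_variance"]


class TestScaling:
    def test_uv_scaling_affine_equivariant(self):
        """Column-wise affine transforms of X leave the UV-scaled matrix
        unchanged, hence the whole model."""
        rng = np.random.default_rng(14)
        X, classes = _two_class_data(rng)
        scale = rng.uniform(0.5, 3.0, X.shape[1])
        shift = rng.normal(0, 10, X.shape[1])
        m1 = fit_opls_da(X, classes)
        m2 = fit_opls_da(X * scale + shift, classes)
        np.testing.assert_allclose(m1.scores, m2.scores, atol=1e-8)
        assert m1.r2y_cum == pytest.approx(m2.r2y_cum, abs=1e-10)

    def test_constant_column_warning(self):
        rng = np.random.default_rng(15)
        classes = np.array(["a"] * 6 + ["b"] * 6)
        X = rng.normal(size=(12, 4))
        X[:, 1] = 3.0
        with pytest.warns(UserWarning, match="constant feature"):
            fit_opls_da(X, classes)

    def test_log_transform_applied(self):
        sc = _fit_scaler(np.array([[9.0], [99.0]]), "center", log_transform=True)
        Z = _apply_scaler(np.array([[9.0], [99.0]]), sc)
        np.testing.assert_allclose(Z[:, 0], [-0.5, 0.5], atol=1e-12)

    def test_unknown_scaling_raises(self):
        with pytest.raises(ValueError):
            _fit_scaler(np.ones((3, 2)), "rank", False)


class TestInputValidation:
    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_opls_da(np.ones((4, 3)), np.array(["a"] * 4))

    def test_zero_predictive_components_raises(self):
        rng = np.random.default_rng(17)
        X, classes = _two_class_data(rng, n_per=4)
        with pytest.raises(ValueError):
            fit_opls_da(X, classes, n_predictive=0)

    def test_predict_round_trip_shapes(self):
        rng = np.random.default_rng(16)
        X, classes = _two_class_data(rng)
        model = fit_opls_da(X, classes)
        Y_hat = model.predict(X)
        assert Y_hat.shape == (len(classes), 2)
        # predictions classify the training samples correctly
        pred_labels = np.array(model.class_labels)[Y_hat.argmax(axis=1)]
        assert (pred_labels == classes).all()
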