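import numpy as np
import pytest

from nirpls.pls_core import (
    calibration_line,
    cross_validate_rmsecv,
    fit_plsr,
    lod,
    loq,
    predict,
    r_squared,
    rmse,
    rsd,
    select_n_lvs,
    variance_contributions,
)


def eigen_pls_oracle(X, Y, n_lvs):
    """Independent PLS2 reference: each weight vector is the dominant
    eigenvector of Xc' Yc Yc' Xc, with the usual deflation.  Returns the
    prediction function and per-LV (w, t, p, q)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    x_mean, y_mean = X.mean(0), Y.mean(0)
    Xc, Yc = X - x_mean, Y - y_mean
    Ws, Ts, Ps, Qs = [], [], [], []
    for _ in range(n_lvs):
        M = Xc.T @ Yc @ Yc.T @ Xc
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        t = Xc @ w
        tt = t @ t
        p = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, q)
        Ws.append(w), Ts.append(t), Ps.append(p), Qs.append(q)
    W, P, Q = (np.column_stack(m) for m in (Ws, Ps, Qs))
    B = W @ np.linalg.solve(P.T @ W, Q.T)

    def pred(X_new):
        return (np.asarray(X_new, float) - x_mean) @ B + y_mean

    return pred, Ws, Ts, Ps, Qs


class TestFitPLSR:
    def test_rank_one_system_fit_exactly_with_one_lv(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=7))
        Y = np.outer(t, rng.normal(size=2))
        model = fit_plsr(X, Y, 1)
        for j in range(Y.shape[1]):
            assert r_squared(Y[:, j], predict(model, X)[:, j]) > 1 - 1e-8
        x_var, _ = variance_contributions(model)
        assert abs(x_var[0] - 100.0) < 1e-6

    def test_full_rank_pls_equals_ols_with_intercept(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 2))
        model = fit_plsr(X, Y, 3)
        X1 = np.column_stack([np.ones(8), X])
        beta = np.linalg.lstsq(X1, Y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), X1 @ beta, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 3))
        model = fit_plsr(X, Y, 3)
        oracle_pred, Ws, Ts, _, _ = eigen_pls_oracle(X, Y, 3)
        for a in range(3):
            w_ref, t_ref = Ws[a], Ts[a]
            sign = np.sign(w_ref @ model.weights[:, a])
            np.testing.assert_allclose(model.weights[:, a], sign * w_ref, atol=1e-8)
            np.testing.assert_allclose(model.scores[:, a], sign * t_ref, atol=1e-8)
        np.testing.assert_allclose(predict(model, X), oracle_pred(X), atol=1e-8)

    def test_matches_sklearn_predictions(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 12))
        Y = 0.5 * X @ rng.normal(size=(12, 3)) + 0.1 * rng.normal(size=(20, 3))
        model = fit_plsr(X, Y, 4)
        ref = sklearn_pls.PLSRegression(
            n_components=4, scale=False, tol=1e-16, max_iter=10_000
        ).fit(X, Y)
        np.testing.assert_allclose(predict(model, X), ref.predict(X), atol=1e-7)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(4)
        model = fit_plsr(rng.normal(size=(15, 8)), rng.normal(size=(15, 3)), 5)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_prediction_self_consistency_and_centering(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 5))
        Y = rng.normal(size=(9, 2))
        model = fit_plsr(X, Y, 2)
        np.testing.assert_allclose(
            predict(model, X),
            (X - model.x_mean) @ model.coefficients + model.y_mean,
            atol=1e-10,
        )
        np.testing.assert_allclose(
            predict(model, model.x_mean[None, :])[0], model.y_mean, atol=1e-10
        )

    def test_constant_y_shift_propagates_to_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=(10, 2))
        m0 = fit_plsr(X, Y, 2)
        m1 = fit_plsr(X, Y + 7.5, 2)
        np.testing.assert_allclose(
            predict(m1, X), predict(m0, X) + 7.5, atol=1e-8
        )

    def test_rmsec_non_increasing_in_n(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 10))
        Y = rng.normal(size=(20, 3))
        errs = []
        for n in range(1, 8):
            model = fit_plsr(X, Y, n)
            errs.append(rmse(Y.ravel(), predict(model, X).ravel()))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_variance_contributions_complete_decomposition(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=(10, 2))
        model = fit_plsr(X, Y, 4)  # min(n-1, p) components
        x_var, y_var = variance_contributions(model)
        assert np.all(x_var >= 0) and np.all(y_var >= 0)
        assert abs(x_var.sum() - 100.0) < 1e-6
        assert y_var.sum() <= 100.0 + 1e-6

    @pytest.mark.parametrize("n_lvs", [0, 10])
    def test_bad_lv_count_rejected(self, n_lvs):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            fit_plsr(rng.normal(size=(8, 5)), rng.normal(size=(8, 2)), n_lvs)

    def test_zero_variance_response_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 5))
        Y = np.column_stack([rng.normal(size=8), np.full(8, 2.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_plsr(X, Y, 2)

    def test_predict_shape_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        model = fit_plsr(rng.normal(size=(8, 5)), rng.normal(size=(8, 2)), 2)
        with pytest.raises(ValueError, match="columns"):
            predict(model, np.zeros((1, 4)))


class TestMetrics:
    def test_r_squared_values(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert r_squared([0, 2], [1, 1]) == pytest.approx(0.0)
        assert r_squared([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8]) == pytest.approx(0.98)

    def test_r_squared_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_rmse_values(self):
        assert rmse([1, 2], [1, 2]) == pytest.approx(0.0)
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        assert rmse([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_rmse_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    def test_rsd_values(self):
        assert rsd([4.0, 5.0, 6.0]) == pytest.approx(20.0)
        assert rsd([3.0, 3.0, 3.0]) == pytest.approx(0.0)
        assert rsd([4.455, 4.545]) == pytest.approx(np.sqrt(2) * 100 * 0.045 / 4.5)

    def test_rsd_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rsd([4.0])
        with pytest.raises(ValueError):
            rsd([-1.0, 1.0])

    def test_lod_loq_formulas(self):
        assert lod(1.0, 1.0) == pytest.approx(3.3)
        assert loq(1.0, 1.0) == pytest.approx(10.0)
        assert lod(0.0, 2.0) == 0.0
        assert lod(0.05, 0.9919) == pytest.approx(0.16635, abs=5e-5)
        assert loq(0.7, 1.3) / lod(0.7, 1.3) == pytest.approx(10 / 3.3)

    def test_lod_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            lod(1.0, 0.0)

    def test_calibration_line_recovers_known_relation(self):
        ref = np.linspace(0, 10, 12)
        pred = 0.1 + 0.95 * ref
        intercept, slope, r2 = calibration_line(ref, pred)
        assert intercept == pytest.approx(0.1)
        assert slope == pytest.approx(0.95)
        assert r2 == pytest.approx(r_squared(ref, pred))


# RMSEC table for component counts 1..10 plus thinned high-N rows, as the
# LV-count rule consumes it: N -> (anhydrate, monohydrate, total) in w/w%.
RMSEC_TABLE = {
    1: (2.4550, 0.7807, 2.0416),
    2: (0.2573, 0.4495, 0.5637),
    3: (0.2348, 0.4166, 0.4922),
    4: (0.2313, 0.2427, 0.3225),
    5: (0.2215, 0.2214, 0.2803),
    6: (0.2209, 0.1886, 0.2594),
    7: (0.1780, 0.1636, 0.2242),
    8: (0.1652, 0.1424, 0.1813),
    9: (0.1377, 0.1458, 0.1655),
    10: (0.1313, 0.1268, 0.1502),
    15: (0.0777, 0.0758, 0.0806),
    20: (0.0410, 0.0567, 0.0519),
    25: (0.0273, 0.0269, 0.0240),
}


class TestSelectNLvs:
    def test_printed_table_selects_five(self):
        assert select_n_lvs(RMSEC_TABLE, threshold=0.3) == 5

    def test_immediately_qualifying_table(self):
        assert select_n_lvs({1: (0.1, 0.1, 0.1), 2: (0.05,) * 3}) == 1

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_n_lvs(RMSEC_TABLE, threshold=0.0)

    def test_no_qualifying_n_advises_extension(self):
        with pytest.raises(ValueError, match="extend"):
            select_n_lvs({1: (1.0, 1.0, 1.0)}, threshold=0.3)


class TestCrossValidation:
    def test_matches_explicit_fold_loop(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 2))
        per, avg = cross_validate_rmsecv(X, Y, 2)
        pred = np.empty_like(Y)
        for i in range(6):
            idx = [j for j in range(6) if j != i]
            m = fit_plsr(X[idx], Y[idx], 2)
            pred[i] = predict(m, X[i : i + 1])[0]
        expected = np.sqrt(np.mean((Y - pred) ** 2, axis=0))
        np.testing.assert_allclose(per, expected, atol=1e-10)
        assert avg == pytest.approx(expected.mean(), abs=1e-10)

    def test_noiseless_rank_one_system_near_zero(self):
        rng = np.random.default_rng(13)
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=5))
        Y = np.outer(t, [1.0, 2.0])
        per, avg = cross_validate_rmsecv(X, Y, 1)
        assert avg <= 1e-6
        assert np.all(per >= 0)

    def test_too_many_lvs_for_loo_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            cross_validate_rmsecv(rng.normal(size=(5, 4)), rng.normal(size=(5, 2)), 4)
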