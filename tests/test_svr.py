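import numpy as np
import pytest

from uvcalib import LinearSVR, fit_linear_svr, predict_svr
from uvcalib.svr import DegenerateGeometryError
from oracles import brute_force_svr_dual, svr_dual_objective


class TestExactLine:
    """Data exactly on c = 2x: a wide tube must contain every residual,
    and with a wide x-span the flattest feasible slope is within 1e-3
    of the true one."""

    def setup_method(self):
        self.x = np.linspace(0.0, 250.0, 10).reshape(-1, 1)
        self.y = 2.0 * self.x.ravel()
        self.model = LinearSVR(epsilon=0.1, C=1000.0).fit(self.x, self.y)

    def test_all_residuals_inside_tube(self):
        resid = np.abs(self.model.predict(self.x) - self.y)
        assert resid.max() <= 0.1 + 1e-8

    def test_implied_slope(self):
        assert self.model.coef_[0] == pytest.approx(2.0, abs=1e-3)


class TestBruteForceOracle:
    @pytest.mark.parametrize("eps,C", [(0.05, 2.0), (0.3, 1.0), (0.0, 5.0)])
    def test_three_point_dual_matches_grid_search(self, eps, C):
        X = np.array([[0.0, 1.0], [1.0, 0.5], [2.0, -0.5]])
        y = np.array([0.2, 1.1, 2.3])
        model = LinearSVR(epsilon=eps, C=C).fit(X, y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        K = Xc @ Xc.T
        best = brute_force_svr_dual(K, yc, eps, C, n_grid=401)
        mine = svr_dual_objective(model.dual_coef_, K, yc, eps)
        # solver must be at least as good as the grid, up to grid resolution
        assert mine >= best - 1e-9
        assert abs(mine - best) <= 1e-3 * max(1.0, abs(best))


class TestSklearnOracle:
    @pytest.mark.parametrize("trial", range(4))
    def test_objective_and_predictions_match_reference(self, trial):
        rng = np.random.default_rng(100 + trial)
        X = rng.normal(size=(12, 7))
        y = X @ rng.normal(size=7) + 0.05 * rng.normal(size=12)
        eps, C = 0.1, 50.0
        model = LinearSVR(epsilon=eps, C=C).fit(X, y)

        from sklearn.svm import SVR

        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        ref = SVR(kernel="linear", C=C, epsilon=eps, tol=1e-10, max_iter=-1)
        ref.fit(Xc, yc)
        beta_ref = np.zeros(12)
        beta_ref[ref.support_] = ref.dual_coef_.ravel()
        K = Xc @ Xc.T
        obj_ref = svr_dual_objective(beta_ref, K, yc, eps)
        obj_mine = svr_dual_objective(model.dual_coef_, K, yc, eps)
        assert abs(obj_mine - obj_ref) <= 1e-6 * max(1.0, abs(obj_ref))
        np.testing.assert_allclose(
            model.predict(X), ref.predict(Xc) + y.mean(), atol=1e-4
        )


class TestKktConditions:
    def fit(self, seed=3, eps=0.1, C=20.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(14, 6))
        y = X @ rng.normal(size=6) + 0.2 * rng.normal(size=14)
        return LinearSVR(epsilon=eps, C=C).fit(X, y), C

    def test_box_and_equality_constraints(self):
        model, C = self.fit()
        beta = model.dual_coef_
        assert np.all(np.abs(beta) <= C + 1e-9)
        assert abs(beta.sum()) <= 1e-8 * C

    def test_complementarity(self):
        # alpha_i * alpha*_i = 0 holds structurally in the beta form:
        # alpha = max(beta, 0), alpha* = max(-beta, 0)
        model, C = self.fit()
        alpha = np.maximum(model.dual_coef_, 0.0)
        alpha_star = np.maximum(-model.dual_coef_, 0.0)
        assert np.all(alpha * alpha_star <= 1e-6 * C**2)
        assert np.all((alpha <= C + 1e-9) & (alpha_star <= C + 1e-9))

    def test_primal_weight_equals_kernel_expansion(self):
        model, _ = self.fit()
        rng = np.random.default_rng(9)
        X_new = rng.normal(size=(5, 6))
        via_w = (X_new - model.x_mean_) @ model.coef_ + model.intercept_ + model.y_mean_
        via_kernel = (
            (X_new - model.x_mean_) @ model.training_vectors_.T @ model.dual_coef_
            + model.intercept_ + model.y_mean_
        )
        np.testing.assert_allclose(via_w, via_kernel, atol=1e-10)

    def test_support_vector_count_monotone_in_epsilon(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=16)
        counts = [
            LinearSVR(epsilon=eps, C=10.0).fit(X, y).support_.size
            for eps in (0.01, 0.05, 0.2, 0.5, 1.0, 2.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestDegenerateCases:
    def test_tube_wider_than_response_spread_gives_zero_model(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        model = LinearSVR(epsilon=10 * np.ptp(y), C=5.0).fit(X, y)
        assert np.all(model.dual_coef_ == 0)
        pred = model.predict(X)
        assert np.ptp(pred) == 0  # constant prediction

    def test_identical_spectra_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(DegenerateGeometryError):
            LinearSVR(epsilon=0.1, C=1.0).fit(X, np.arange(5.0))

    def test_parameter_validation(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.arange(5.0)
        with pytest.raises(ValueError, match="epsilon"):
            LinearSVR(epsilon=-0.1, C=1.0).fit(X, y)
        with pytest.raises(ValueError, match="C must"):
            LinearSVR(epsilon=0.1, C=0.0).fit(X, y)


class TestContainerWrappers:
    def test_fit_predict_within_tube_on_noiseless_data(self, noiseless_scenario):
        X_tr, c_tr, X_te, c_te = noiseless_scenario
        model, state = fit_linear_svr(X_tr, c_tr, "CEF", epsilon=0.01, penalty=1000.0)
        resid = np.abs(predict_svr(model, X_tr) - c_tr.column("CEF"))
        assert resid.max() <= 0.01 + 1e-6

    def test_grid_mismatch_rejected(self, noiseless_scenario):
        X_tr, c_tr, _, _ = noiseless_scenario
        model, _ = fit_linear_svr(X_tr, c_tr, "CEF", epsilon=0.1, penalty=100.0)
        from uvcalib.io import SpectraMatrix

        other = SpectraMatrix(
            samples=["x"], wavelengths=X_tr.wavelengths[:-1] + 0.5,
            values=np.zeros((1, X_tr.n_wavelengths - 1)),
        )
        with pytest.raises(ValueError, match="grid"):
            predict_svr(model, other)


def test_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    X = rng.normal(size=(10, 5))
    y = X @ rng.normal(size=5)
    model = LinearSVR(epsilon=0.05, C=30.0).fit(X, y)
    path = tmp_path / "svr.json"
    model.save(path)
    back = LinearSVR.load(path)
    np.testing.assert_allclose(back.predict(X), model.predict(X), rtol=1e-12)
    np.testing.assert_array_equal(back.support_, model.support_)
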