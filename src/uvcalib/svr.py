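"""Linear epsilon-insensitive support vector regression (dual form).

Training solves the standard epsilon-SVR dual

    max  -1/2 sum_ij (a_i - a*_i)(a_j - a*_j) x_i.x_j
         - eps sum_i (a_i + a*_i) + sum_i y_i (a_i - a*_i)
    s.t. 0 <= a_i, a*_i <= C,   sum_i (a_i - a*_i) = 0,

written in the equivalent single-variable form beta_i = a_i - a*_i
(at the optimum a_i a*_i = 0, so |beta_i| = a_i + a*_i):

    min  1/2 b' K b - y' b + eps ||b||_1,   sum b = 0,  |b_i| <= C,

with K the Gram matrix of the centered spectra.  The solver is an
SMO-style pairwise coordinate descent (see `_dual_solver`): each step
picks the maximal-violating pair (i, j) and moves beta along e_i - e_j
(preserving the equality constraint) to the exact minimizer of the
piecewise-quadratic restriction, stopping when the worst pairwise KKT
violation falls below `tol`.

The prediction function is f(x) = sum_i beta_i (x_i . x) + b on
centered data; the bias b comes from the KKT conditions, averaged over
unbounded support vectors (midpoint of the feasible KKT interval if
none exist).  X and y are mean-centered internally with training means.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._dual_solver import solve_dual
from .io import ConcentrationTable, SpectraMatrix
from .preprocess import CenteringState, fit_center

__all__ = ["LinearSVR", "SvrConvergenceError", "DegenerateGeometryError",
           "fit_linear_svr", "predict_svr"]


class SvrConvergenceError(RuntimeError):
    """Dual solver did not converge within its iteration budget."""


class DegenerateGeometryError(ValueError):
    """All training spectra identical: the dual has no informative solution."""


def _solve_dual(K: np.ndarray, y: np.ndarray, eps: float, C: float,
                tol: float, max_iter: int) -> np.ndarray:
    """Solve the beta-form dual via the SMO kernel; see `_dual_solver`."""
    scale = max(1.0, float(np.abs(y).max()))
    beta, converged, violation = solve_dual(K, y, eps, C, tol * scale, max_iter)
    if not converged:
        raise SvrConvergenceError(
            f"dual solver did not converge within {max_iter} iterations "
            f"(remaining KKT violation {violation:.3e})"
        )
    return beta


class LinearSVR(RegressorMixin, BaseEstimator):
    """Linear epsilon-SVR trained in the dual.

    Parameters
    ----------
    epsilon : float
        Half-width of the insensitive tube (same units as y, which is
        centered internally so only differences matter).
    C : float
        Box constraint / regularization trade-off; larger C penalizes
        tube violations more.
    tol : float
        KKT-violation threshold for convergence (relative to the
        response scale).
    max_iter : int
        Budget of pair updates; exceeded -> :class:`SvrConvergenceError`.

    Attributes
    ----------
    dual_coef_ : (I,) values beta_i = alpha_i - alpha*_i.
    coef_ : (J,) primal weight vector w = sum_i beta_i x_i (centered x).
    intercept_ : bias b on the centered-response scale.
    support_ : indices with |beta_i| > 1e-8 * C.
    training_vectors_ : centered training spectra (rows used in the
        kernel expansion of the prediction function).
    x_mean_, y_mean_ : training means.
    dual_objective_ : attained value of the (maximization-form) dual.
    """

    _SV_RTOL = 1e-8

    def __init__(self, epsilon: float = 0.1, C: float = 100.0,
                 tol: float = 1e-9, max_iter: int = 5_000_000):
        self.epsilon = epsilon
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.C <= 0:
            raise ValueError("C must be positive")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        if not np.any(np.abs(Xc) > 0):
            raise DegenerateGeometryError(
                "all training spectra are identical; the regression "
                "direction is undefined"
            )
        K = Xc @ Xc.T
        beta = _solve_dual(K, yc, float(self.epsilon), float(self.C),
                           float(self.tol), int(self.max_iter))

        self.dual_coef_ = beta
        self.training_vectors_ = Xc
        self.coef_ = Xc.T @ beta
        self.support_ = np.flatnonzero(np.abs(beta) > self._SV_RTOL * self.C)
        self.intercept_ = self._kkt_bias(K, yc, beta)
        Kb = K @ beta
        self.dual_objective_ = float(
            -0.5 * beta @ Kb - self.epsilon * np.abs(beta).sum() + yc @ beta
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _kkt_bias(self, K: np.ndarray, yc: np.ndarray, beta: np.ndarray) -> float:
        """Bias from KKT: unbounded SVs sit exactly on the tube edge."""
        eps, C = float(self.epsilon), float(self.C)
        Kb = K @ beta
        sv_tol = self._SV_RTOL * C
        bound_tol = C * (1.0 - 1e-6)
        free = np.flatnonzero(
            (np.abs(beta) > sv_tol) & (np.abs(beta) < bound_tol)
        )
        if free.size:
            # beta_i > 0: y_i - f(x_i) = +eps;  beta_i < 0: = -eps
            vals = yc[free] - Kb[free] - eps * np.sign(beta[free])
            return float(vals.mean())
        # no free SVs: intersect the per-sample KKT intervals for b
        lo, hi = -np.inf, np.inf
        for i in range(beta.size):
            r = yc[i] - Kb[i]
            if abs(beta[i]) <= sv_tol:
                lo, hi = max(lo, r - eps), min(hi, r + eps)
            elif beta[i] >= bound_tol:
                hi = min(hi, r - eps)
            else:
                lo = max(lo, r + eps)
        if not np.isfinite(lo):
            lo = hi
        if not np.isfinite(hi):
            hi = lo
        return float((lo + hi) / 2.0) if np.isfinite(lo) else 0.0

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        Xc = X - self.x_mean_
        # kernel-expansion form of Eq. f(x) = sum_i beta_i (x_i.x) + b
        return Xc @ self.coef_ + self.intercept_ + self.y_mean_

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model": "linear-svr",
            "epsilon": float(self.epsilon),
            "C": float(self.C),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "training_vectors": self.training_vectors_.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSVR":
        if d.get("model") != "linear-svr":
            raise ValueError("not a serialized linear SVR model")
        m = cls(epsilon=d["epsilon"], C=d["C"])
        m.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        m.intercept_ = float(d["intercept"])
        m.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        m.y_mean_ = float(d["y_mean"])
        m.training_vectors_ = np.asarray(d["training_vectors"], dtype=float)
        m.coef_ = m.training_vectors_.T @ m.dual_coef_
        m.support_ = np.flatnonzero(
            np.abs(m.dual_coef_) > cls._SV_RTOL * m.C
        )
        m.n_features_in_ = m.x_mean_.shape[0]
        return m

    @classmethod
    def load(cls, path) -> "LinearSVR":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Container-level wrappers
# ---------------------------------------------------------------------------

def fit_linear_svr(
    X: SpectraMatrix,
    c: ConcentrationTable,
    component: str,
    epsilon: float,
    penalty: float,
) -> tuple[LinearSVR, CenteringState]:
    """Fit linear SVR for one named component of a concentration table."""
    state = fit_center(X, c)
    model = LinearSVR(epsilon=epsilon, C=penalty)
    model.fit(X.values, c.column(component))
    model.grid_ = X.wavelengths.copy()
    return model, state


def predict_svr(model: LinearSVR, X_new: SpectraMatrix) -> np.ndarray:
    """Predict concentrations (ug/mL) for new spectra on the fitted grid."""
    if hasattr(model, "grid_") and not np.array_equal(model.grid_, X_new.wavelengths):
        raise ValueError("wavelength grid does not match the fitted grid")
    return model.predict(X_new.values)
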