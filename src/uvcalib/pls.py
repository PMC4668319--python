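"""PLS1: partial least squares regression for a single response.

The model is the bilinear decomposition

    X = T P + E,        c = T q + f,

with scores ``T`` (I x A), X-loadings ``P`` (A x J), response loadings
``q`` (A,), and residuals ``E``, ``f``; A is the number of latent
variables.  Components are extracted by the classical NIPALS deflation
for one response (orthogonal-scores convention, X deflated only): for
each component the weight vector is w = X'c / ||X'c|| (no inner
iteration is needed with a single response), the score is t = X w, and
X is deflated by t p'.

Prediction maps centered spectra through the weights and loadings:
b = W (P W)^-1 q, then adds back the training response mean.  With A
equal to the pseudo-rank of the centered X and noise-free linear data,
training predictions reproduce c exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .io import ConcentrationTable, SpectraMatrix
from .preprocess import CenteringState, fit_center

__all__ = ["PLS1Regression", "fit_pls1", "predict_pls1"]


class PLS1Regression(RegressorMixin, BaseEstimator):
    """Single-response PLS regression (NIPALS, orthogonal scores).

    Parameters
    ----------
    n_components : int
        Number of latent variables A; must satisfy
        ``1 <= A <= min(I - 1, J)``.
    rank_tol : float
        Early-stop guard: extraction halts (with a warning) if the
        residual X norm falls below ``rank_tol`` times the original, and
        the model keeps the components extracted so far.

    Attributes
    ----------
    x_weights_ : (A, J) weight vectors W, unit norm.
    x_loadings_ : (A, J) loadings P.
    y_loadings_ : (A,) response loadings q.
    scores_ : (I, A) training scores T, mutually orthogonal.
    coef_ : (J,) regression vector b on centered data.
    x_mean_, y_mean_ : training means used for centering.
    x_residual_, y_residual_ : training residuals E (I x J) and f (I,).
    """

    def __init__(self, n_components: int = 2, rank_tol: float = 1e-12):
        self.n_components = n_components
        self.rank_tol = rank_tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        I, J = X.shape
        if y.shape[0] != I:
            raise ValueError("X and y must have the same number of rows")
        A = int(self.n_components)
        if A < 1 or A > min(I - 1, J):
            raise ValueError(
                f"n_components={A} out of range 1..{min(I - 1, J)} "
                f"for data of shape {X.shape}"
            )
        if np.ptp(y) == 0:
            raise ValueError("response has zero variance; nothing to model")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        x_norm0 = np.linalg.norm(Xc)

        W = np.zeros((A, J))
        P = np.zeros((A, J))
        q = np.zeros(A)
        T = np.zeros((I, A))
        E, f = Xc.copy(), yc.copy()
        n_extracted = 0
        for a in range(A):
            if np.linalg.norm(E) < self.rank_tol * x_norm0:
                warnings.warn(
                    f"residual X exhausted after {a} components; "
                    f"returning a {a}-component model",
                    stacklevel=2,
                )
                break
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw == 0:
                warnings.warn(
                    f"response residual uncorrelated with X after {a} "
                    f"components; returning a {a}-component model",
                    stacklevel=2,
                )
                break
            w /= nw
            t = E @ w
            tt = float(t @ t)
            p = (E.T @ t) / tt
            qa = float(f @ t) / tt
            E = E - np.outer(t, p)
            f = f - qa * t
            W[a], P[a], q[a], T[:, a] = w, p, qa, t
            n_extracted = a + 1

        self.n_components_ = n_extracted
        W, P, q, T = W[:n_extracted], P[:n_extracted], q[:n_extracted], T[:, :n_extracted]
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.scores_ = T
        self.x_residual_ = E
        self.y_residual_ = f
        # b = W'(P W')^-1 q  with W, P stored as (A, J)
        self.coef_ = W.T @ np.linalg.solve(P @ W.T, q)
        self.n_features_in_ = J
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model": "pls1",
            "n_components": int(self.n_components_),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PLS1Regression":
        if d.get("model") != "pls1":
            raise ValueError("not a serialized PLS1 model")
        m = cls(n_components=d["n_components"])
        m.n_components_ = d["n_components"]
        m.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        m.y_mean_ = float(d["y_mean"])
        m.x_weights_ = np.asarray(d["x_weights"], dtype=float)
        m.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        m.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.n_features_in_ = m.coef_.shape[0]
        return m

    @classmethod
    def load(cls, path) -> "PLS1Regression":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Container-level wrappers
# ---------------------------------------------------------------------------

def fit_pls1(
    X: SpectraMatrix,
    c: ConcentrationTable,
    component: str,
    n_components: int,
) -> tuple[PLS1Regression, CenteringState]:
    """Fit PLS1 for one named component of a concentration table."""
    state = fit_center(X, c)
    model = PLS1Regression(n_components=n_components)
    model.fit(X.values, c.column(component))
    model.grid_ = X.wavelengths.copy()
    return model, state


def predict_pls1(model: PLS1Regression, X_new: SpectraMatrix) -> np.ndarray:
    """Predict concentrations (ug/mL) for new spectra on the fitted grid."""
    if hasattr(model, "grid_") and not np.array_equal(model.grid_, X_new.wavelengths):
        raise ValueError("wavelength grid does not match the fitted grid")
    return model.predict(X_new.values)
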