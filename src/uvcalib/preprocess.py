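"""Mean centering of spectra and responses.

Mean centering is the only preprocessing the calibration uses: column
means of the training spectra and the mean of each response are stored
at fit time and subtracted from any later data, so test samples are
always centered with *training* statistics (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ConcentrationTable, SpectraMatrix

__all__ = ["CenteringState", "MeanCenterer", "fit_center", "apply_center"]


@dataclass(frozen=True)
class CenteringState:
    """Frozen training means: spectral column means (AU) on a fixed grid
    plus one response mean (ug/mL) per component."""

    wavelengths: np.ndarray
    column_means: np.ndarray
    response_means: dict[str, float]

    def center_spectra(self, X: SpectraMatrix) -> SpectraMatrix:
        if not np.array_equal(X.wavelengths, self.wavelengths):
            raise ValueError("wavelength grid does not match the fitted grid")
        return SpectraMatrix(
            samples=list(X.samples),
            wavelengths=X.wavelengths.copy(),
            values=X.values - self.column_means,
        )

    def center_response(self, c: np.ndarray, component: str) -> np.ndarray:
        return np.asarray(c, dtype=float) - self.response_means[component]

    def uncenter_response(self, c: np.ndarray, component: str) -> np.ndarray:
        return np.asarray(c, dtype=float) + self.response_means[component]


def fit_center(X: SpectraMatrix, c: ConcentrationTable | None = None) -> CenteringState:
    """Compute training column means of X and per-component response means."""
    if X.n_samples < 2:
        raise ValueError("need at least 2 samples to fit centering")
    response_means = {}
    if c is not None:
        response_means = {
            name: float(c.column(name).mean()) for name in c.components
        }
    return CenteringState(
        wavelengths=X.wavelengths.copy(),
        column_means=X.values.mean(axis=0),
        response_means=response_means,
    )


def apply_center(state: CenteringState, X: SpectraMatrix) -> SpectraMatrix:
    """Subtract the stored training column means from X."""
    return state.center_spectra(X)


class MeanCenterer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer view of spectral mean centering.

    Operates on plain 2-D arrays so it composes with sklearn pipelines;
    `CenteringState` is the package-level equivalent for the labeled
    containers.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError("feature count does not match the fitted data")
        return X - self.mean_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) + self.mean_
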