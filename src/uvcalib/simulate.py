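"""Synthetic UV mixture spectra with the structure the calibration assumes.

Real spectra of the cefoperazone system are not publicly deposited, so
this module generates stand-ins with the same statistical structure:
three heavily overlapped pure-component UV absorbers, Beer-Lambert
linear mixing on the calibration design concentrations, and additive
homoscedastic Gaussian instrument noise.

Pure spectra are sums of Gaussian bands.  The defaults emulate the real
system qualitatively: the major analyte (CEF) peaks at 229 nm, the two
impurities absorb in the same window with pairwise spectral cosine
similarity >= 0.7 against CEF, and impurity concentrations sit near 1%
of the major component (by mass), so the mixtures are dominated by CEF.
Band centers/widths/intensities are fixtures, not fits to the real
compounds, and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignTable, cef_test_design, cef_training_design
from .io import DEFAULT_GRID, ConcentrationTable, SpectraMatrix, Spectrum

__all__ = [
    "GaussianBand",
    "PureSpectrumModel",
    "NoiseModel",
    "pure_spectrum",
    "mix_spectra",
    "default_pure_models",
    "default_scenario",
    "DEFAULT_SIGMA",
]

#: Default additive noise level, AU — a typical double-beam UV noise floor.
DEFAULT_SIGMA = 0.002


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (nm), width (nm, Gaussian sigma), and
    peak specific absorbance (AU per ug/mL at 1 cm path)."""

    center: float
    width: float
    coeff: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.coeff < 0:
            raise ValueError("band coefficient must be non-negative")


@dataclass(frozen=True)
class PureSpectrumModel:
    """Pure-component spectrum as a sum of Gaussian bands.

    Absorbance is linear in concentration (Beer-Lambert):
    ``A(lambda) = conc * sum_b coeff_b * exp(-(lambda-center_b)^2 / (2 width_b^2))``.
    """

    component: str
    bands: tuple[GaussianBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("need at least one band")

    def specific_absorbance(self, grid: np.ndarray) -> np.ndarray:
        """Absorbance per ug/mL on the given grid (unit concentration)."""
        grid = np.asarray(grid, dtype=float)
        out = np.zeros_like(grid)
        for b in self.bands:
            out += b.coeff * np.exp(-((grid - b.center) ** 2) / (2 * b.width**2))
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive iid Gaussian instrument noise, sigma in AU."""

    sigma: float = DEFAULT_SIGMA
    seed: int = 0
    kind: str = "additive-gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "additive-gaussian":
            raise ValueError(f"unsupported noise kind {self.kind!r}")

    def sample(self, shape) -> np.ndarray:
        if self.sigma == 0:
            return np.zeros(shape)
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.sigma, size=shape)


def pure_spectrum(
    model: PureSpectrumModel,
    grid: np.ndarray = DEFAULT_GRID,
    concentration: float = 1.0,
) -> Spectrum:
    """Noise-free spectrum of one component at the given concentration."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    grid = np.asarray(grid, dtype=float)
    return Spectrum(
        wavelengths=grid,
        absorbances=concentration * model.specific_absorbance(grid),
        label=f"{model.component}@{concentration:g}",
    )


def mix_spectra(
    models: dict[str, PureSpectrumModel],
    design: DesignTable,
    grid: np.ndarray = DEFAULT_GRID,
    noise: NoiseModel | None = None,
) -> tuple[SpectraMatrix, ConcentrationTable]:
    """Beer-Lambert mixtures of the design rows, plus additive noise.

    ``X[i, j] = sum_f c[i, f] * s_f(lambda_j) + e[i, j]`` with
    ``e ~ N(0, sigma^2)`` iid from the noise model's seeded generator.
    """
    if set(models) != set(design.components):
        raise ValueError(
            f"model components {sorted(models)} do not match design "
            f"components {sorted(design.components)}"
        )
    grid = np.asarray(grid, dtype=float)
    # F x J pure spectra at unit concentration, in design component order
    S = np.vstack(
        [models[name].specific_absorbance(grid) for name in design.components]
    )
    X = design.concentrations @ S
    if noise is not None:
        X = X + noise.sample(X.shape)
    spectra = SpectraMatrix(
        samples=list(design.row_labels),
        wavelengths=grid,
        values=X,
    )
    return spectra, design.to_concentration_table()


def default_pure_models() -> dict[str, PureSpectrumModel]:
    """Default band fixtures for the three-component system.

    CEF peaks at 229 nm and gives roughly 1 AU per 10 ug/mL, the scale
    of a typical mid-range UV assay.  The impurity bands sit close to
    CEF's (pairwise spectral cosine similarity 0.86-0.97), reproducing
    the heavy overlap that makes univariate quantification impossible.

    The impurities' per-mass peak intensities are much larger than
    CEF's.  Two effects are folded in: per microgram, small molecules
    absorb more strongly (molecular weights: CEF sodium 667.7, 7-ACA
    272.3, 5-MER 116.1 g/mol), and the intensities are additionally
    scaled up so that at their trace design levels (about 1% of CEF by
    mass) each impurity perturbs the mixture spectra well above the
    0.002 AU noise floor.  That places the simulation in the regime the
    calibration method is for — a genuinely three-dimensional signal
    with every direction above noise — while CEF still dominates every
    mixture's total absorbance.  The bands are fixtures, not fits to
    the real compounds, and can be overridden.
    """
    return {
        "CEF": PureSpectrumModel("CEF", (
            GaussianBand(center=229.0, width=16.0, coeff=0.11),
        )),
        "7-ACA": PureSpectrumModel("7-ACA", (
            GaussianBand(center=236.0, width=17.0, coeff=2.70),
        )),
        "5-MER": PureSpectrumModel("5-MER", (
            GaussianBand(center=224.0, width=14.0, coeff=6.32),
        )),
    }


def default_scenario(
    seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    models: dict[str, PureSpectrumModel] | None = None,
    grid: np.ndarray = DEFAULT_GRID,
) -> tuple[SpectraMatrix, ConcentrationTable, SpectraMatrix, ConcentrationTable]:
    """Full simulated study: 16 training + 9 test mixtures on the default
    design, default overlapped pure spectra, additive noise.

    Returns ``(X_train, c_train, X_test, c_test)``; training and test
    noise are drawn from independent streams derived from ``seed``.
    """
    if models is None:
        models = default_pure_models()
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    X_tr, c_tr = mix_spectra(
        models, cef_training_design(), grid,
        NoiseModel(sigma=sigma, seed=int(seeds[0])),
    )
    X_te, c_te = mix_spectra(
        models, cef_test_design(), grid,
        NoiseModel(sigma=sigma, seed=int(seeds[1])),
    )
    return X_tr, c_tr, X_te, c_te
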