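import numpy as np
import pytest

from uvcalib import (
    GaussianBand,
    NoiseModel,
    PureSpectrumModel,
    cef_training_design,
    default_pure_models,
    default_scenario,
    mix_spectra,
    pure_spectrum,
)
from uvcalib.design import COMPONENTS
from uvcalib.io import DEFAULT_GRID


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestPureSpectrum:
    def test_cef_peaks_at_229nm(self):
        s = pure_spectrum(default_pure_models()["CEF"], concentration=10.0)
        assert s.wavelengths[np.argmax(s.absorbances)] == 229.0

    def test_zero_concentration_gives_zero_spectrum(self):
        s = pure_spectrum(default_pure_models()["CEF"], concentration=0.0)
        assert np.all(s.absorbances == 0)

    def test_beer_lambert_linearity(self):
        model = default_pure_models()["5-MER"]
        s1 = pure_spectrum(model, concentration=1.5)
        s2 = pure_spectrum(model, concentration=3.0)
        np.testing.assert_allclose(s2.absorbances, 2 * s1.absorbances, rtol=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            pure_spectrum(default_pure_models()["CEF"], concentration=-1.0)

    def test_band_invariants(self):
        with pytest.raises(ValueError, match="width"):
            GaussianBand(center=229.0, width=0.0, coeff=1.0)
        with pytest.raises(ValueError, match="coefficient"):
            GaussianBand(center=229.0, width=1.0, coeff=-1.0)
        with pytest.raises(ValueError, match="band"):
            PureSpectrumModel("x", ())


class TestMixSpectra:
    def test_noiseless_single_component_rows_equal_pure_spectra(self):
        design = cef_training_design()
        models = default_pure_models()
        X, c = mix_spectra(models, design, noise=None)
        # single-component check via a one-component design
        from uvcalib.design import DesignTable

        one = DesignTable(components=["CEF"],
                          concentrations=design.concentrations[:, :1])
        X1, _ = mix_spectra({"CEF": models["CEF"]}, one, noise=None)
        for i in range(one.n_mixtures):
            expected = pure_spectrum(models["CEF"],
                                     concentration=one.concentrations[i, 0])
            np.testing.assert_allclose(X1.values[i], expected.absorbances, rtol=1e-12)

    def test_noiseless_mixtures_have_rank_three(self):
        # SVD of the noiseless matrix as the oracle: exactly 3 nonzero
        # singular values
        X, _ = mix_spectra(default_pure_models(), cef_training_design(), noise=None)
        s = np.linalg.svd(X.values, compute_uv=False)
        assert s[2] > 1e-6
        assert s[3] < 1e-10 * s[0]

    def test_fixed_seed_reproducible(self):
        noise = NoiseModel(sigma=0.002, seed=42)
        X1, _ = mix_spectra(default_pure_models(), cef_training_design(), noise=noise)
        X2, _ = mix_spectra(default_pure_models(), cef_training_design(), noise=noise)
        np.testing.assert_array_equal(X1.values, X2.values)

    def test_component_name_mismatch_rejected(self):
        models = default_pure_models()
        models.pop("5-MER")
        with pytest.raises(ValueError, match="match"):
            mix_spectra(models, cef_training_design())

    def test_mixing_is_linear_in_the_design(self):
        # mix(A) + mix(B) == spectra of (A concentrations + B concentrations)
        from uvcalib.design import DesignTable

        models = default_pure_models()
        d = cef_training_design()
        a = DesignTable(components=d.components, concentrations=d.concentrations)
        b = DesignTable(components=d.components,
                        concentrations=d.concentrations[::-1].copy())
        ab = DesignTable(components=d.components,
                         concentrations=a.concentrations + b.concentrations)
        Xa, _ = mix_spectra(models, a, noise=None)
        Xb, _ = mix_spectra(models, b, noise=None)
        Xab, _ = mix_spectra(models, ab, noise=None)
        np.testing.assert_allclose(Xab.values, Xa.values + Xb.values, rtol=1e-12)


class TestDefaultScenario:
    def test_output_shapes(self, scenario):
        X_tr, c_tr, X_te, c_te = scenario
        assert X_tr.values.shape == (16, 91)
        assert c_tr.values.shape == (16, 3)
        assert X_te.values.shape == (9, 91)
        assert c_te.values.shape == (9, 3)

    def test_pure_spectra_heavily_overlapped(self):
        # pairwise cosine similarity >= 0.7, by direct dot products
        models = default_pure_models()
        S = [models[n].specific_absorbance(DEFAULT_GRID) for n in COMPONENTS]
        for i in range(3):
            for j in range(i + 1, 3):
                assert cosine(S[i], S[j]) >= 0.7

    def test_major_component_dominates_every_mixture(self, scenario):
        X_tr, c_tr, _, _ = scenario
        models = default_pure_models()
        S = np.vstack([models[n].specific_absorbance(X_tr.wavelengths)
                       for n in COMPONENTS])
        cef = np.outer(c_tr.column("CEF"), S[0])
        total = c_tr.values @ S
        fraction = cef.sum(axis=1) / total.sum(axis=1)
        assert fraction.min() > 0.5

    def test_impurities_are_trace_level(self, scenario):
        _, c_tr, _, _ = scenario
        cef = c_tr.column("CEF")
        for name in ("7-ACA", "5-MER"):
            assert np.all(c_tr.column(name) / cef < 0.02)

    def test_noiseless_matrix_lies_in_pure_spectra_span(self, noiseless_scenario):
        X_tr, _, _, _ = noiseless_scenario
        models = default_pure_models()
        S = np.vstack([models[n].specific_absorbance(X_tr.wavelengths)
                       for n in COMPONENTS])
        # residual after projecting each row onto span(S)
        proj = S.T @ np.linalg.solve(S @ S.T, S @ X_tr.values.T)
        assert np.abs(X_tr.values.T - proj).max() < 1e-10

    def test_scenario_deterministic_in_seed(self):
        a = default_scenario(seed=9)
        b = default_scenario(seed=9)
        c = default_scenario(seed=10)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert not np.array_equal(a[0].values, c[0].values)


def test_noise_model_invariants():
    with pytest.raises(ValueError, match="non-negative"):
        NoiseModel(sigma=-0.1)
    with pytest.raises(ValueError, match="kind"):
        NoiseModel(kind="pink")
    assert np.all(NoiseModel(sigma=0.0).sample((3, 4)) == 0)
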