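import numpy as np
import pytest

from uvcalib import (
    bootstrap_select_lv,
    cef_training_design,
    default_pure_models,
    default_scenario,
    mix_spectra,
    rmsecv_grid_search,
    rmsep,
)
from uvcalib.design import COMPONENTS, DesignTable
from uvcalib.model_selection import _pls1_prediction_path
from uvcalib.simulate import NoiseModel


class TestRmsep:
    def test_perfect_prediction_is_zero(self):
        assert rmsep([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        assert rmsep([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))

    def test_single_pair(self):
        assert rmsep([20.0], [19.85]) == pytest.approx(0.15)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            rmsep([], [])
        with pytest.raises(ValueError, match="equal length"):
            rmsep([1.0], [1.0, 2.0])


def rank_limited_scenario(rank, sigma=0.0, seed=0):
    """Mixtures built from only the first `rank` pure components."""
    models = default_pure_models()
    design = cef_training_design()
    keep = COMPONENTS[:rank]
    sub = DesignTable(
        components=keep,
        concentrations=design.concentrations[:, :rank].copy(),
    )
    noise = NoiseModel(sigma=sigma, seed=seed) if sigma > 0 else None
    X, c = mix_spectra({k: models[k] for k in keep}, sub, noise=noise)
    return X, c.column("CEF")


class TestBootstrapSelectLv:
    @pytest.mark.parametrize("rank", [1, 2, 3])
    def test_noiseless_pseudo_rank_recovered(self, rank):
        X, y = rank_limited_scenario(rank)
        res = bootstrap_select_lv(X, y, max_components=6, n_iterations=50, seed=4)
        assert res.selected_components == rank

    def test_default_scenario_selects_three_components(self, scenario):
        X_tr, c_tr, _, _ = scenario
        res = bootstrap_select_lv(X_tr, c_tr.column("CEF"),
                                  max_components=8, n_iterations=1000, seed=11)
        assert res.selected_components == 3

    def test_selection_near_rank_under_moderate_noise(self):
        # sigma=0.005 AU: pick within +/-1 of the true rank on >= 8/10 seeds
        hits = 0
        for seed in range(10):
            X, c, _, _ = default_scenario(seed=seed, sigma=0.005)
            res = bootstrap_select_lv(X, c.column("CEF"), max_components=8,
                                      n_iterations=300, seed=500 + seed)
            hits += abs(res.selected_components - 3) <= 1
        assert hits >= 8

    def test_deterministic_only_for_equal_seeds(self, scenario):
        X_tr, c_tr, _, _ = scenario
        y = c_tr.column("CEF")
        a = bootstrap_select_lv(X_tr, y, 5, n_iterations=50, seed=1)
        b = bootstrap_select_lv(X_tr, y, 5, n_iterations=50, seed=1)
        c = bootstrap_select_lv(X_tr, y, 5, n_iterations=50, seed=2)
        np.testing.assert_array_equal(a.mean_rmsep, b.mean_rmsep)
        assert not np.array_equal(a.mean_rmsep, c.mean_rmsep)

    def test_with_replacement_mode_runs(self, scenario):
        X_tr, c_tr, _, _ = scenario
        res = bootstrap_select_lv(X_tr, c_tr.column("CEF"), 5,
                                  n_iterations=50, seed=3, with_replacement=True)
        assert 1 <= res.selected_components <= 5

    def test_infeasible_component_budget_rejected(self, scenario):
        X_tr, c_tr, _, _ = scenario
        with pytest.raises(ValueError, match="infeasible"):
            bootstrap_select_lv(X_tr, c_tr.column("CEF"), max_components=11,
                                n_iterations=10, seed=0)

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="at least 6"):
            bootstrap_select_lv(X, np.arange(5.0), 2, n_iterations=5, seed=0)

    def test_zero_margin_recovers_plain_argmin(self, scenario):
        X_tr, c_tr, _, _ = scenario
        y = c_tr.column("CEF")
        res = bootstrap_select_lv(X_tr, y, 8, n_iterations=200, seed=6,
                                  parsimony_margin=0.0)
        assert res.selected_components == int(np.argmin(res.mean_rmsep)) + 1


class TestPredictionPath:
    def test_path_columns_match_individual_fits(self, rng):
        from uvcalib import PLS1Regression

        X = rng.normal(size=(10, 12))
        y = rng.normal(size=10)
        X_new = rng.normal(size=(4, 12))
        path = _pls1_prediction_path(X, y, X_new, 5)
        for a in range(1, 6):
            direct = PLS1Regression(n_components=a).fit(X, y).predict(X_new)
            np.testing.assert_allclose(path[:, a - 1], direct, atol=1e-10)


class TestRmsecvGridSearch:
    def test_single_point_grid_is_selected(self, scenario):
        X_tr, c_tr, _, _ = scenario
        res = rmsecv_grid_search(X_tr, c_tr.column("CEF"),
                                 epsilon_grid=[0.1], penalty_grid=[100.0], seed=0)
        assert res.selected == (0.1, 100.0)
        assert res.mean_rmsecv.shape == (1, 1)

    def test_narrow_tube_beats_wide_tube_on_noiseless_data(self, noiseless_scenario):
        X_tr, c_tr, _, _ = noiseless_scenario
        res = rmsecv_grid_search(X_tr, c_tr.column("CEF"),
                                 epsilon_grid=[0.01, 1.0],
                                 penalty_grid=[30.0, 1000.0], seed=1)
        table = res.to_frame()
        assert table.loc[0.01, 1000.0] < table.loc[1.0, 30.0]

    def test_folds_partition_all_samples(self, scenario):
        X_tr, c_tr, _, _ = scenario
        res = rmsecv_grid_search(X_tr, c_tr.column("CEF"),
                                 epsilon_grid=[0.1], penalty_grid=[100.0],
                                 n_folds=4, seed=5)
        counts = np.bincount(res.fold_assignment, minlength=4)
        assert res.fold_assignment.size == 16
        np.testing.assert_array_equal(counts, [4, 4, 4, 4])

    def test_rmsecv_equals_pooled_rmsep_identity(self, scenario):
        # recompute one grid point by hand from the stored fold assignment
        from uvcalib import LinearSVR

        X_tr, c_tr, _, _ = scenario
        y = c_tr.column("CEF")
        eps, C = 0.1, 100.0
        res = rmsecv_grid_search(X_tr, y, epsilon_grid=[eps],
                                 penalty_grid=[C], n_folds=4, seed=8)
        known, predicted = [], []
        for k in range(4):
            te = res.fold_assignment == k
            model = LinearSVR(epsilon=eps, C=C).fit(X_tr.values[~te], y[~te])
            predicted.extend(model.predict(X_tr.values[te]))
            known.extend(y[te])
        assert res.mean_rmsecv[0, 0] == pytest.approx(rmsep(known, predicted))

    def test_indivisible_fold_count_rejected(self, scenario):
        X_tr, c_tr, _, _ = scenario
        with pytest.raises(ValueError, match="divide"):
            rmsecv_grid_search(X_tr, c_tr.column("CEF"), n_folds=5)

    def test_empty_grid_rejected(self, scenario):
        X_tr, c_tr, _, _ = scenario
        with pytest.raises(ValueError, match="non-empty"):
            rmsecv_grid_search(X_tr, c_tr.column("CEF"), epsilon_grid=[])
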