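"""End-to-end analysis pipeline: data, hyperparameter selection, model
fits, evaluation, plots, and a structured run log.

The pipeline either simulates the default study (16 training + 9 test
mixtures on the balanced design, overlapped pure spectra, additive
noise) or loads spectra/concentration CSVs, then:

1. selects the PLS component count by bootstrap RMSEP,
2. selects the SVR hyperparameters (epsilon, C) by 4-fold RMSECV grid
   search,
3. fits both calibration models for the analyte of interest,
4. writes taken/found/recovery reports (RMSEC on the training set,
   RMSEP on the test set), serialized models, selection tables, plots,
   and a JSON-lines log of every seed and selected hyperparameter,
5. optionally compares each model's recovery statistics against a
   reference method's summary statistics by t- and F-tests.

All randomness flows from the seeds in :class:`RunConfig`; identical
configurations produce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .design import cef_test_design, cef_training_design
from .evaluation import assay_report, compare_to_reference
from .io import (
    ConcentrationTable,
    SpectraMatrix,
    read_concentration_csv,
    read_spectra_csv,
    write_concentration_table,
    write_spectra_csv,
)
from .model_selection import (
    DEFAULT_EPSILON_GRID,
    DEFAULT_PENALTY_GRID,
    bootstrap_select_lv,
    rmsecv_grid_search,
)
from .pls import PLS1Regression
from .simulate import DEFAULT_SIGMA, default_scenario
from .svr import LinearSVR

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full run.

    ``mode`` is "simulate" (generate the default scenario) or "load"
    (read the four CSV paths).  Seeds are split per stochastic stage so
    stages can be reproduced independently.
    """

    mode: str = "simulate"
    component: str = "CEF"
    # simulate mode
    sigma: float = DEFAULT_SIGMA
    simulation_seed: int = 0
    # load mode
    train_spectra: str | None = None
    train_concentrations: str | None = None
    test_spectra: str | None = None
    test_concentrations: str | None = None
    # model selection
    bootstrap_iterations: int = 1000
    lv_max: int = 8
    bootstrap_seed: int = 1
    parsimony_margin: float = 0.15
    epsilon_grid: tuple = DEFAULT_EPSILON_GRID
    penalty_grid: tuple = DEFAULT_PENALTY_GRID
    n_folds: int = 4
    fold_seed: int = 2
    # evaluation
    alpha: float = 0.05
    reference: dict | None = None  # {"mean":..., "sd":..., "n":...}
    # output
    out_dir: str = "uvcalib-run"
    plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def validate(self, n_train: int | None = None) -> None:
        if self.mode not in ("simulate", "load"):
            raise PipelineError(f"config: mode must be simulate|load, got {self.mode!r}")
        if self.mode == "load":
            paths = [self.train_spectra, self.train_concentrations,
                     self.test_spectra, self.test_concentrations]
            if any(p is None for p in paths):
                raise PipelineError("config: load mode needs all four data paths")
            for p in paths:
                if not Path(p).exists():
                    raise PipelineError(f"config: missing input file {p}")
        if n_train is not None and n_train % self.n_folds != 0:
            raise PipelineError(
                f"config: n_folds={self.n_folds} does not divide the "
                f"{n_train} training samples"
            )
        if self.bootstrap_iterations < 1 or self.lv_max < 1:
            raise PipelineError("config: iterations and lv_max must be positive")


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _load_data(config: RunConfig):
    if config.mode == "simulate":
        return default_scenario(seed=config.simulation_seed, sigma=config.sigma)
    X_tr = read_spectra_csv(config.train_spectra)
    c_tr = read_concentration_csv(config.train_concentrations)
    X_te = read_spectra_csv(config.test_spectra)
    c_te = read_concentration_csv(config.test_concentrations)
    return X_tr, c_tr, X_te, c_te


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_file = log_path.open("w")

    def log(stage: str, **payload) -> None:
        log_file.write(json.dumps({"stage": stage, **payload}) + "\n")
        log_file.flush()

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    config.validate()
    X_tr, c_tr, X_te, c_te = stage("data")(_load_data, config)
    config.validate(n_train=X_tr.n_samples)
    y_tr = c_tr.column(config.component)
    y_te = c_te.column(config.component)
    log("data", mode=config.mode, component=config.component,
        n_train=X_tr.n_samples, n_test=X_te.n_samples,
        sigma=config.sigma if config.mode == "simulate" else None,
        simulation_seed=config.simulation_seed if config.mode == "simulate" else None,
        x_train_sha=_sha(X_tr.values), x_test_sha=_sha(X_te.values))
    if config.mode == "simulate":
        write_spectra_csv(X_tr, out / "train_spectra.csv")
        write_spectra_csv(X_te, out / "test_spectra.csv")
        write_concentration_table(c_tr, out / "train_concentrations.csv")
        write_concentration_table(c_te, out / "test_concentrations.csv")

    lv = stage("select-lv")(
        bootstrap_select_lv, X_tr, y_tr,
        max_components=config.lv_max,
        n_iterations=config.bootstrap_iterations,
        seed=config.bootstrap_seed,
        parsimony_margin=config.parsimony_margin,
    )
    lv.to_json(out / "lv_selection.json")
    lv.to_frame().to_csv(out / "lv_selection.csv", index=False)
    log("select-lv", selected=lv.selected_components,
        iterations=lv.n_iterations, seed=lv.seed,
        mean_rmsep=[round(v, 6) for v in lv.mean_rmsep])

    grid = stage("select-svr")(
        rmsecv_grid_search, X_tr, y_tr,
        epsilon_grid=config.epsilon_grid,
        penalty_grid=config.penalty_grid,
        n_folds=config.n_folds,
        seed=config.fold_seed,
    )
    grid.to_csv(out / "svr_grid.csv")
    grid.to_json(out / "svr_selection.json")
    log("select-svr", epsilon=grid.selected_epsilon, C=grid.selected_penalty,
        seed=grid.seed, n_folds=config.n_folds)

    pls = stage("fit-pls")(
        lambda: PLS1Regression(n_components=lv.selected_components).fit(X_tr.values, y_tr)
    )
    svr = stage("fit-svr")(
        lambda: LinearSVR(epsilon=grid.selected_epsilon, C=grid.selected_penalty).fit(X_tr.values, y_tr)
    )
    pls.save(out / "pls_model.json")
    svr.save(out / "svr_model.json")
    log("fit", pls_components=lv.selected_components,
        svr_epsilon=grid.selected_epsilon, svr_C=grid.selected_penalty,
        svr_support_vectors=int(svr.support_.size))

    summary: dict = {
        "selected_components": lv.selected_components,
        "selected_epsilon": grid.selected_epsilon,
        "selected_penalty": grid.selected_penalty,
    }
    reports = {}
    for name, model in (("pls", pls), ("svr", svr)):
        train_rep = assay_report(y_tr, model.predict(X_tr.values), role="calibration")
        test_rep = assay_report(y_te, model.predict(X_te.values), role="prediction")
        reports[name] = (train_rep, test_rep)
        for rep, tag in ((train_rep, "train"), (test_rep, "test")):
            rep.to_frame().to_csv(out / f"{name}_{tag}_report.csv", index=False)
        (out / f"{name}_report.txt").write_text(
            f"== calibration (training set) ==\n{train_rep.to_text()}\n\n"
            f"== prediction (test set) ==\n{test_rep.to_text()}\n"
        )
        summary[name] = {
            "rmsec": train_rep.rmse,
            "rmsep": test_rep.rmse,
            "train_mean_recovery": train_rep.mean_recovery,
            "test_mean_recovery": test_rep.mean_recovery,
            "test_sd_recovery": test_rep.sd_recovery,
        }
        log("evaluate", model=name, **{k: round(v, 6) for k, v in summary[name].items()})

    if config.reference is not None:
        ref = config.reference
        for name in ("pls", "svr"):
            test_rep = reports[name][1]
            cmp_ = compare_to_reference(
                test_rep.mean_recovery, test_rep.sd_recovery, len(test_rep.taken),
                float(ref["mean"]), float(ref["sd"]), int(ref["n"]),
                alpha=config.alpha,
            )
            (out / f"{name}_vs_reference.txt").write_text(cmp_.to_text() + "\n")
            summary[name]["t_statistic"] = cmp_.t_statistic
            summary[name]["f_statistic"] = cmp_.f_statistic
            log("compare", model=name, t=round(cmp_.t_statistic, 4),
                f=round(cmp_.f_statistic, 4),
                t_critical=round(cmp_.t_critical, 4),
                f_critical=round(cmp_.f_critical, 4))

    if config.plots:
        from .plots import plot_design_scores, plot_rmsep_comparison, plot_rmsep_vs_lv

        stage("plots")(plot_rmsep_vs_lv, lv, out / "rmsep_vs_lv.png")
        stage("plots")(
            plot_rmsep_comparison,
            {"PLSR": reports["pls"][1].rmse, "linear SVR": reports["svr"][1].rmse},
            out / "rmsep_comparison.png",
        )
        if config.mode == "simulate":
            stage("plots")(
                plot_design_scores, cef_training_design(), cef_test_design(),
                out / "design_scores.png",
            )

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    log_file.close()
    return summary
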