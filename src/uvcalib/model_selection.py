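"""Hyperparameter selection for the two calibration models.

Two procedures:

* PLS latent-variable count: Monte-Carlo "bootstrap" selection.  The
  training set is repeatedly split at random into two-thirds (bootstrap
  training) and one-third (bootstrap test); for every candidate number
  of components A the bootstrap-training model predicts the held-out
  third and an RMSEP is recorded.  Selected is the smallest A whose
  mean RMSEP over all iterations (1000 by default) sits within a small
  parsimony margin of the curve minimum — see
  :func:`bootstrap_select_lv` for why a raw argmin is not used.  The
  split is without replacement (the set is *divided*); a
  with-replacement resampling mode is available for sensitivity checks.

* SVR (epsilon, C): exhaustive grid search scored by k-fold
  cross-validated RMSECV (4 folds of 4 on the 16-mixture design: each
  fold is predicted by a model trained on the remaining 12).  Default
  grids are log-spaced over epsilon in [0.01, 1] and C in [30, 1000];
  ties go to smaller C, then smaller epsilon.

Both RMSEP and RMSECV are root mean squared errors over held-out
predictions, RMSE = sqrt( sum_n (c_n - chat_n)^2 / N ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SpectraMatrix
from .svr import LinearSVR

__all__ = [
    "rmsep",
    "bootstrap_select_lv",
    "rmsecv_grid_search",
    "BootstrapLvResult",
    "GridSearchResult",
    "DEFAULT_EPSILON_GRID",
    "DEFAULT_PENALTY_GRID",
]

#: Default search grids spanning the documented hyperparameter ranges.
DEFAULT_EPSILON_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
DEFAULT_PENALTY_GRID = (30.0, 56.0, 100.0, 180.0, 280.0, 560.0, 1000.0)


def rmsep(known, predicted) -> float:
    """Root mean square error sqrt( sum (c - chat)^2 / N ), ug/mL."""
    known = np.asarray(known, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if known.size == 0:
        raise ValueError("need at least one (known, predicted) pair")
    if known.shape != predicted.shape:
        raise ValueError("known and predicted must have equal length")
    return float(np.sqrt(np.mean((known - predicted) ** 2)))


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, SpectraMatrix) else np.asarray(X, float)


def _pls1_prediction_path(Xtr, ytr, Xte, a_max: int) -> np.ndarray:
    """Held-out PLS1 predictions for every A in 1..a_max in one pass.

    Runs the NIPALS deflation once with internal centering and
    accumulates the test prediction component by component; column a of
    the result is the prediction at A = a + 1 components.
    """
    xm, ym = Xtr.mean(axis=0), ytr.mean()
    E = Xtr - xm
    f = ytr - ym
    Ete = Xte - xm
    preds = np.empty((Xte.shape[0], a_max))
    acc = np.zeros(Xte.shape[0])
    for a in range(a_max):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:  # response exhausted; later columns repeat
            preds[:, a:] = (acc + ym)[:, None]
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        p = (E.T @ t) / tt
        qa = float(f @ t) / tt
        t_new = Ete @ w
        acc += qa * t_new
        preds[:, a] = acc + ym
        E -= np.outer(t, p)
        f -= qa * t
        Ete -= np.outer(t_new, p)
    return preds


@dataclass
class BootstrapLvResult:
    """Mean held-out RMSEP per candidate component count, and the pick."""

    candidate_components: np.ndarray
    mean_rmsep: np.ndarray
    n_iterations: int
    selected_components: int
    seed: int
    parsimony_margin: float = 0.0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "candidate_components": self.candidate_components.tolist(),
            "mean_rmsep": self.mean_rmsep.tolist(),
            "n_iterations": self.n_iterations,
            "selected_components": self.selected_components,
            "seed": self.seed,
            "parsimony_margin": self.parsimony_margin,
        }, indent=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_components": self.candidate_components,
            "mean_rmsep": self.mean_rmsep,
        })


def bootstrap_select_lv(
    X,
    c,
    max_components: int,
    n_iterations: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
    parsimony_margin: float = 0.15,
) -> BootstrapLvResult:
    """Select the PLS component count by repeated 2/3-1/3 splitting.

    Every iteration draws a fresh split, mean-centers the bootstrap
    training part, fits PLS1 for each candidate A and accumulates the
    RMSEP on the held-out third.  Reproducible for a fixed ``seed``.

    The pick is the smallest A whose mean RMSEP lies within
    ``parsimony_margin`` (relative) of the curve minimum.  A plain
    argmin is unreliable here: the Monte-Carlo mean curve typically
    falls steeply up to the signal pseudo-rank and then drifts by
    fractions of a percent, so its global minimum wanders over the flat
    tail from realization to realization while the model barely
    changes.  The margin (15% by default, in the spirit of the
    PRESS-ratio rule of Haaland & Thomas) makes the choice land at the
    start of the plateau; set it to 0 for the raw argmin, with exact
    ties still resolved toward fewer components.
    """
    X = _values(X)
    y = np.asarray(c, dtype=float).ravel()
    I = X.shape[0]
    if y.shape[0] != I:
        raise ValueError("X and c must have the same number of rows")
    if I < 6:
        raise ValueError("need at least 6 samples for a 2/3-1/3 split")
    n_train = int(round(2 * I / 3))
    n_test = I - n_train
    if max_components < 1 or max_components > n_train - 1:
        raise ValueError(
            f"max_components={max_components} infeasible: bootstrap "
            f"training size is {n_train}, so 1..{n_train - 1} is allowed"
        )
    if n_iterations < 1:
        raise ValueError("n_iterations must be positive")

    rng = np.random.default_rng(seed)
    total = np.zeros(max_components)
    for _ in range(n_iterations):
        if with_replacement:
            tr = rng.integers(0, I, size=n_train)
            te = np.setdiff1d(np.arange(I), np.unique(tr))
            if te.size == 0:  # degenerate resample: redraw deterministic split
                te = rng.choice(I, size=n_test, replace=False)
                tr = np.setdiff1d(np.arange(I), te)
        else:
            perm = rng.permutation(I)
            tr, te = perm[:n_train], perm[n_train:]
        preds = _pls1_prediction_path(X[tr], y[tr], X[te], max_components)
        total += np.sqrt(np.mean((preds - y[te, None]) ** 2, axis=0))

    mean_rmsep = total / n_iterations
    candidates = np.arange(1, max_components + 1)
    # absolute guard so exact-fit curves (values ~ machine epsilon) are
    # compared sensibly
    threshold = (1.0 + parsimony_margin) * mean_rmsep.min() + 1e-8 * float(np.std(y))
    selected = int(candidates[int(np.flatnonzero(mean_rmsep <= threshold)[0])])
    return BootstrapLvResult(
        candidate_components=candidates,
        mean_rmsep=mean_rmsep,
        n_iterations=n_iterations,
        selected_components=selected,
        seed=seed,
        parsimony_margin=parsimony_margin,
    )


@dataclass
class GridSearchResult:
    """RMSECV surface over the (epsilon, C) grid, folds, and the pick."""

    epsilon_grid: np.ndarray
    penalty_grid: np.ndarray
    mean_rmsecv: np.ndarray  # len(epsilon_grid) x len(penalty_grid)
    selected_epsilon: float
    selected_penalty: float
    fold_assignment: np.ndarray  # fold index per sample
    seed: int

    @property
    def selected(self) -> tuple[float, float]:
        return (self.selected_epsilon, self.selected_penalty)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean_rmsecv,
            index=pd.Index(self.epsilon_grid, name="epsilon"),
            columns=pd.Index(self.penalty_grid, name="C"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "selected_epsilon": self.selected_epsilon,
            "selected_penalty": self.selected_penalty,
            "seed": self.seed,
            "fold_assignment": self.fold_assignment.tolist(),
        }, indent=1))


def rmsecv_grid_search(
    X,
    c,
    epsilon_grid=DEFAULT_EPSILON_GRID,
    penalty_grid=DEFAULT_PENALTY_GRID,
    n_folds: int = 4,
    seed: int = 0,
) -> GridSearchResult:
    """Grid-search (epsilon, C) for linear SVR by k-fold RMSECV.

    Folds are a seeded random partition into ``n_folds`` equal parts
    (``n_folds`` must divide the sample count); every held-out fold is
    predicted by a model trained — with its own centering — on the
    remaining samples, and RMSECV pools all I held-out predictions.
    """
    X = _values(X)
    y = np.asarray(c, dtype=float).ravel()
    I = X.shape[0]
    if y.shape[0] != I:
        raise ValueError("X and c must have the same number of rows")
    eps_grid = np.asarray(epsilon_grid, dtype=float)
    c_grid = np.asarray(penalty_grid, dtype=float)
    if eps_grid.size == 0 or c_grid.size == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    if n_folds < 2 or I % n_folds != 0:
        raise ValueError(
            f"n_folds={n_folds} must be >= 2 and divide the sample count {I}"
        )

    rng = np.random.default_rng(seed)
    perm = rng.permutation(I)
    fold_of = np.empty(I, dtype=int)
    for k in range(n_folds):
        fold_of[perm[k::n_folds]] = k

    surface = np.empty((eps_grid.size, c_grid.size))
    for a, eps in enumerate(eps_grid):
        for b, C in enumerate(c_grid):
            sq = 0.0
            for k in range(n_folds):
                te = fold_of == k
                model = LinearSVR(epsilon=float(eps), C=float(C))
                model.fit(X[~te], y[~te])
                sq += float(np.sum((model.predict(X[te]) - y[te]) ** 2))
            surface[a, b] = np.sqrt(sq / I)

    best = surface.min()
    # ties toward smaller C, then smaller epsilon
    ties = np.argwhere(surface == best)
    ties = ties[np.lexsort((ties[:, 0], ties[:, 1]))]
    ia, ib = ties[0]
    return GridSearchResult(
        epsilon_grid=eps_grid,
        penalty_grid=c_grid,
        mean_rmsecv=surface,
        selected_epsilon=float(eps_grid[ia]),
        selected_penalty=float(c_grid[ib]),
        fold_assignment=fold_of,
        seed=seed,
    )
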