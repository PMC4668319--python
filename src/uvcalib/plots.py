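"""Diagnostic plots (headless-safe; all output goes to files)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .design import DesignTable
from .model_selection import BootstrapLvResult

__all__ = ["plot_rmsep_vs_lv", "plot_rmsep_comparison", "plot_design_scores"]


def plot_rmsep_vs_lv(result: BootstrapLvResult, path) -> None:
    """Mean bootstrap RMSEP against the number of PLS components."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.candidate_components, result.mean_rmsep, "o-")
    ax.axvline(result.selected_components, color="crimson", ls="--", lw=1,
               label=f"selected A = {result.selected_components}")
    ax.set_xlabel("number of PLS components")
    ax.set_ylabel("mean RMSEP (µg/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rmsep_comparison(rmseps: dict[str, float], path) -> None:
    """Bar chart of test-set RMSEP per model."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    names = list(rmseps)
    ax.bar(names, [rmseps[k] for k in names], color=["steelblue", "darkorange"][: len(names)])
    ax.set_ylabel("RMSEP (µg/mL)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_design_scores(training: DesignTable, test: DesignTable | None, path) -> None:
    """Scatter of the first two principal components of the mean-centered
    concentration matrix — a visual check of design symmetry/rotatability."""
    conc = training.concentrations
    centered = conc - conc.mean(axis=0)
    # scale columns to unit variance so all components are comparable
    centered = centered / centered.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :2] * s[:2]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(scores[:, 0], scores[:, 1], facecolors="none",
               edgecolors="steelblue", label="training")
    if test is not None:
        tc = test.concentrations - conc.mean(axis=0)
        tc = tc / conc.std(axis=0, ddof=1)
        ts = tc @ vt.T[:, :2]
        ax.scatter(ts[:, 0], ts[:, 1], marker="x", color="crimson", label="test")
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend()
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
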