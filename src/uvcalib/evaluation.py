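"""Figures of merit and statistical method comparison.

Assay quality is summarized per sample set as taken vs found
concentration, percent recovery (100 * found / taken), the mean and SD
of the recoveries, and the root mean square error — RMSEC when the set
is the calibration (training) data predicted by its own model
(autoprediction), RMSEP when it is an independent test set.

Agreement with a reference method is assessed on summary statistics:
a variance-ratio F-test (larger variance in the numerator, critical
value from the F distribution at the matching degrees of freedom) and a
pooled-variance two-sample Student's t-test, both two-sided at a given
alpha (0.05 by default).  A computed statistic below its critical value
means no significant difference in precision (F) or trueness (t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayReport",
    "MethodComparison",
    "assay_report",
    "f_test",
    "two_sample_t_test",
    "critical_values",
    "compare_to_reference",
]


@dataclass
class AssayReport:
    """Taken/found/recovery table with summary statistics."""

    taken: np.ndarray
    found: np.ndarray
    recovery: np.ndarray  # percent
    mean_recovery: float
    sd_recovery: float
    rmse: float
    role: str  # "calibration" -> RMSEC, "prediction" -> RMSEP

    @property
    def rmse_name(self) -> str:
        return "RMSEC" if self.role == "calibration" else "RMSEP"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taken_ug_per_mL": self.taken,
            "found_ug_per_mL": self.found,
            "recovery_percent": self.recovery,
        })

    def to_text(self) -> str:
        lines = [f"{'Taken':>8} {'Found':>10} {'R%':>8}"]
        for t, f, r in zip(self.taken, self.found, self.recovery):
            lines.append(f"{t:>8g} {f:>10.3f} {r:>8.2f}")
        lines.append(f"Mean (%)  {self.mean_recovery:.2f}")
        lines.append(f"SD        {self.sd_recovery:.4f}")
        lines.append(f"{self.rmse_name}     {self.rmse:.4f}")
        return "\n".join(lines)


def assay_report(taken, found, role: str = "prediction") -> AssayReport:
    """Build the taken/found/recovery summary for one sample set."""
    taken = np.asarray(taken, dtype=float).ravel()
    found = np.asarray(found, dtype=float).ravel()
    if taken.size == 0 or taken.shape != found.shape:
        raise ValueError("taken and found must be equal-length and non-empty")
    if role not in ("calibration", "prediction"):
        raise ValueError("role must be 'calibration' or 'prediction'")
    zeros = np.flatnonzero(taken == 0)
    if zeros.size:
        raise ZeroDivisionError(
            f"taken concentration is zero at row index {int(zeros[0])}; "
            "recovery is undefined"
        )
    recovery = 100.0 * found / taken
    rmse = float(np.sqrt(np.mean((taken - found) ** 2)))
    # sample SD (ddof=1) as conventional for assay repeatability summaries
    sd = float(np.std(recovery, ddof=1)) if recovery.size > 1 else 0.0
    return AssayReport(
        taken=taken,
        found=found,
        recovery=recovery,
        mean_recovery=float(recovery.mean()),
        sd_recovery=sd,
        rmse=rmse,
        role=role,
    )


def f_test(
    candidate_variance: float,
    reference_variance: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Variance-ratio F-test: larger variance over smaller.

    Degrees of freedom follow the numerator/denominator ordering, so the
    result is invariant to argument order.  Returns
    (f_statistic, f_critical, significant).
    """
    if candidate_variance <= 0 or reference_variance <= 0:
        raise ValueError("variances must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 on both sides")
    if candidate_variance >= reference_variance:
        v_num, v_den, df_num, df_den = candidate_variance, reference_variance, n1 - 1, n2 - 1
    else:
        v_num, v_den, df_num, df_den = reference_variance, candidate_variance, n2 - 1, n1 - 1
    f_stat = v_num / v_den
    f_crit = float(stats.f.ppf(1.0 - alpha, df_num, df_den))
    return float(f_stat), f_crit, bool(f_stat > f_crit)


def two_sample_t_test(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns (|t_statistic|, t_critical two-tailed, significant).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 on both sides")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0 and mean1 != mean2:
        raise ZeroDivisionError(
            "both SDs are zero with unequal means: t statistic is infinite"
        )
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t_stat = 0.0 if mean1 == mean2 else abs(mean1 - mean2) / se
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return float(t_stat), t_crit, bool(t_stat > t_crit)


def critical_values(
    alpha: float,
    df_t: int,
    df_f: tuple[int, int],
) -> tuple[float, float]:
    """Two-tailed t and upper-tail F critical values."""
    if df_t <= 0 or df_f[0] <= 0 or df_f[1] <= 0:
        raise ValueError("degrees of freedom must be positive")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df_t))
    f_crit = float(stats.f.ppf(1.0 - alpha, df_f[0], df_f[1]))
    return t_crit, f_crit


@dataclass
class MethodComparison:
    """t/F comparison of a candidate assay against a reference method."""

    candidate_mean: float
    candidate_sd: float
    candidate_n: int
    reference_mean: float
    reference_sd: float
    reference_n: int
    t_statistic: float
    f_statistic: float
    t_critical: float
    f_critical: float
    alpha: float

    @property
    def t_significant(self) -> bool:
        return self.t_statistic > self.t_critical

    @property
    def f_significant(self) -> bool:
        return self.f_statistic > self.f_critical

    def to_text(self) -> str:
        return "\n".join([
            f"{'':<12}{'Candidate':>12}{'Reference':>12}",
            f"{'Mean':<12}{self.candidate_mean:>12.2f}{self.reference_mean:>12.2f}",
            f"{'SD':<12}{self.candidate_sd:>12.3f}{self.reference_sd:>12.3f}",
            f"{'Variance':<12}{self.candidate_sd**2:>12.3f}{self.reference_sd**2:>12.3f}",
            f"{'n':<12}{self.candidate_n:>12d}{self.reference_n:>12d}",
            f"t-test ({self.t_critical:.3f}): {self.t_statistic:.3f}"
            f" -> {'significant' if self.t_significant else 'not significant'}",
            f"F-test ({self.f_critical:.3f}): {self.f_statistic:.3f}"
            f" -> {'significant' if self.f_significant else 'not significant'}",
        ])


def compare_to_reference(
    candidate_mean: float, candidate_sd: float, candidate_n: int,
    reference_mean: float, reference_sd: float, reference_n: int,
    alpha: float = 0.05,
) -> MethodComparison:
    """Full protocol: pooled t on means, variance-ratio F on precisions."""
    t_stat, t_crit, _ = two_sample_t_test(
        candidate_mean, candidate_sd, candidate_n,
        reference_mean, reference_sd, reference_n, alpha,
    )
    f_stat, f_crit, _ = f_test(
        candidate_sd**2, reference_sd**2, candidate_n, reference_n, alpha,
    )
    return MethodComparison(
        candidate_mean=candidate_mean, candidate_sd=candidate_sd,
        candidate_n=candidate_n, reference_mean=reference_mean,
        reference_sd=reference_sd, reference_n=reference_n,
        t_statistic=t_stat, f_statistic=f_stat,
        t_critical=t_crit, f_critical=f_crit, alpha=alpha,
    )
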