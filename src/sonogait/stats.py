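"""Curve-similarity metrics and group-level statistics.

Prediction quality per curve is summarized by Pearson's r, absolute RMSE
(xBW) and relative RMSE in percent of the reference curve's range. Group
comparisons use paired t-tests with Cohen's d, and one-way repeated-measures
ANOVA across conditions (microphone combinations). Correlation strengths are
bucketed with the conventional low/moderate/strong taxonomy, which leaves
gaps (r <= 0.1 and 0.3 < r <= 0.4) reported as ``unclassified`` rather than
silently absorbed into a neighbouring class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "PredictionQuality",
    "curve_similarity",
    "paired_t",
    "rm_anova",
    "classify_correlation",
    "ci_of_mean",
]


@dataclass(frozen=True)
class PredictionQuality:
    pearson_r: float          # NaN when either curve has zero variance
    rmse_xbw: float
    rrmse_pct: float

    def __post_init__(self) -> None:
        if not math.isnan(self.pearson_r) and not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.rmse_xbw < 0 or self.rrmse_pct < 0:
            raise ValueError("RMSE values must be non-negative")


def curve_similarity(real: np.ndarray, pred: np.ndarray, normalizer: str = "range") -> PredictionQuality:
    """Pearson r, RMSE and relative RMSE between two curves on one grid.

    rRMSE is normalized by the *real* curve — its range by default, its peak
    with ``normalizer='peak'`` — and expressed in percent. Zero-variance
    inputs leave r as NaN (correlation undefined).
    """
    real = np.asarray(real, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if real.shape != pred.shape or real.ndim != 1:
        raise ValueError("curves must be 1-D arrays on the same grid")
    if len(real) < 3:
        raise ValueError("need at least 3 grid points")
    if np.std(real) == 0 or np.std(pred) == 0:
        r = float("nan")
    else:
        r = float(spstats.pearsonr(real, pred).statistic)
    rmse = float(np.sqrt(np.mean((real - pred) ** 2)))
    if normalizer == "range":
        denom = float(real.max() - real.min())
    elif normalizer == "peak":
        denom = float(np.abs(real).max())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    rrmse = 100.0 * rmse / denom if denom > 0 else float("inf") if rmse > 0 else 0.0
    return PredictionQuality(pearson_r=r, rmse_xbw=rmse, rrmse_pct=rrmse)


def paired_t(real_vals: np.ndarray, pred_vals: np.ndarray, d_method: str = "pooled") -> tuple[float, float, float]:
    """Paired t-test with Cohen's d: returns ``(t, p, d)``.

    Cohen's d uses the SD pooled across the two conditions by default (the
    convention that makes d comparable across paired and unpaired designs);
    ``d_method='difference'`` scales by the SD of the paired differences
    instead. Zero-variance differences are degenerate: t = 0, p = 1.
    """
    real_vals = np.asarray(real_vals, dtype=float)
    pred_vals = np.asarray(pred_vals, dtype=float)
    if real_vals.shape != pred_vals.shape or len(real_vals) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = real_vals - pred_vals
    if np.std(diff, ddof=1) == 0:
        return 0.0, 1.0, 0.0
    res = spstats.ttest_rel(real_vals, pred_vals)
    if d_method == "pooled":
        sd = math.sqrt((np.var(real_vals, ddof=1) + np.var(pred_vals, ddof=1)) / 2.0)
    elif d_method == "difference":
        sd = float(np.std(diff, ddof=1))
    else:
        raise ValueError(f"unknown d_method {d_method!r}")
    d = float(np.mean(diff) / sd) if sd > 0 else 0.0
    return float(res.statistic), float(res.pvalue), d


def rm_anova(values: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on a complete subjects x conditions matrix.

    Returns the F statistic with ``(k-1, (k-1)(n-1))`` degrees of freedom and
    its p-value. No sphericity correction is applied. Identical columns give
    F = 0; for two conditions F equals the squared paired-t statistic.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells are not supported")
    n, k = values.shape
    if np.allclose(values, values[:, :1]):  # all conditions identical: F = 0 by definition
        return 0.0, 1.0
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "value": values.ravel(),
        }
    )
    table = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit().anova_table
    return float(table["F Value"].iloc[0]), float(table["Pr > F"].iloc[0])


def classify_correlation(r: float) -> str:
    """Bucket a correlation: low (0.1, 0.3], moderate (0.4, 0.7], strong (> 0.7).

    Values in the taxonomy's gaps (|r| <= 0.1 or 0.3 < r <= 0.4) come back
    ``unclassified``. Classification uses the magnitude of r.
    """
    if not math.isfinite(r):
        raise ValueError("r must be finite")
    m = abs(r)
    if m > 0.7:
        return "strong"
    if 0.4 < m <= 0.7:
        return "moderate"
    if 0.1 < m <= 0.3:
        return "low"
    return "unclassified"


def ci_of_mean(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval ``mean +/- z * sd / sqrt(n)``."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 2:
        raise ValueError("n must be >= 2")
    z = float(spstats.norm.ppf(0.5 + level / 2.0))
    half = z * sd / math.sqrt(n)
    return mean - half, mean + half
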