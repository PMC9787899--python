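"""End-to-end experiment: LOSO sweeps, style-accuracy and variable tables.

Ties the predictor, metrics and statistics layers together the way the full
study runs: leave-one-subject-out prediction for each requested microphone
combination, per-curve quality metrics, foot-strike style accuracy per
runner, and a group-level comparison of the biomechanical variables
extracted from real vs predicted curves (paired t, Cohen's d, per-runner
RMSE), with per-subject averaging before any group statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import classify_style_from_vgrf, extract_variables, style_accuracy
from .predictor import DEFAULT_GRID, MIC_COMBINATIONS, TrialRecord, loso_evaluate
from .signal_processing import StanceCurve
from .stats import ci_of_mean, paired_t, rm_anova

__all__ = ["run_experiment", "style_table", "variable_comparison", "subject_summary"]

#: biomechanical variables compared between real and predicted curves
_VARIABLES = [
    "impact_peak_xbw",
    "t_impact_peak_pct",
    "active_peak_xbw",
    "t_active_peak_pct",
    "lr1_xbw_s",
    "lr2_xbw_s",
    "lr3_xbw_s",
    "impulse_xbw_pct",
]


def _as_curve(values: np.ndarray, stance_time_s: float, grid: np.ndarray) -> StanceCurve:
    return StanceCurve(values=np.asarray(values), times=grid * stance_time_s, normalized=True)


def subject_summary(loso: pd.DataFrame) -> pd.DataFrame:
    """Average the per-trial quality metrics within each runner."""
    return (
        loso.groupby(["combo", "subject_id"], as_index=False)[["pearson_r", "rmse_xbw", "rrmse_pct"]]
        .mean()
        .sort_values(["combo", "subject_id"], ignore_index=True)
    )


def style_table(loso: pd.DataFrame, grid: np.ndarray = DEFAULT_GRID) -> pd.DataFrame:
    """Per-combination foot-strike accuracy summary (one row per combo).

    Style is read off both the real and the predicted curve of every trial;
    accuracy is the fraction of agreeing trials per runner, then summarized
    across runners by mean, SD, median and the 95% normal CI, in percent.
    """
    rows = []
    for combo, block in loso.groupby("combo"):
        per_subject = []
        for _, subj_block in block.groupby("subject_id"):
            real = [classify_style_from_vgrf(_as_curve(r.real_curve, r.stance_time_s, grid)) for r in subj_block.itertuples()]
            pred = [classify_style_from_vgrf(_as_curve(r.pred_curve, r.stance_time_s, grid)) for r in subj_block.itertuples()]
            per_subject.append(100.0 * style_accuracy(real, pred))
        acc = np.asarray(per_subject)
        lo, hi = ci_of_mean(acc.mean(), acc.std(ddof=1), len(acc)) if len(acc) >= 2 else (np.nan, np.nan)
        rows.append(
            {"combo": combo, "mean_pct": acc.mean(), "sd_pct": acc.std(ddof=1) if len(acc) >= 2 else 0.0,
             "median_pct": float(np.median(acc)), "ci_lower_pct": lo, "ci_upper_pct": hi, "n_subjects": len(acc)}
        )
    return pd.DataFrame(rows)


def variable_comparison(loso: pd.DataFrame, grid: np.ndarray = DEFAULT_GRID) -> pd.DataFrame:
    """Group comparison of biomech variables from real vs predicted curves.

    Variables are extracted per trial from both curves, averaged within
    runner, then compared across runners with a paired t-test and Cohen's d;
    the RMSE column is the across-runner mean +/- SD of each runner's
    per-trial RMSE. Output mirrors the conventional real/pred summary table.
    """
    recs = []
    for r in loso.itertuples():
        rv = extract_variables(_as_curve(r.real_curve, r.stance_time_s, grid))
        pv = extract_variables(_as_curve(r.pred_curve, r.stance_time_s, grid))
        for var in _VARIABLES:
            recs.append({"subject_id": r.subject_id, "variable": var,
                         "real": getattr(rv, var), "pred": getattr(pv, var)})
    df = pd.DataFrame(recs).dropna()
    rows = []
    for var in _VARIABLES:
        block = df[df["variable"] == var]
        per_subj = block.groupby("subject_id").agg(
            real=("real", "mean"), pred=("pred", "mean"),
            rmse=("real", lambda s: np.nan),  # placeholder, filled below
        )
        rmse_by_subj = block.groupby("subject_id").apply(
            lambda b: float(np.sqrt(np.mean((b["real"] - b["pred"]) ** 2))), include_groups=False
        )
        per_subj["rmse"] = rmse_by_subj
        if len(per_subj) >= 2:
            t, p, d = paired_t(per_subj["real"].to_numpy(), per_subj["pred"].to_numpy())
        else:
            t = p = d = np.nan
        rows.append(
            {"variable": var,
             "real_mean": per_subj["real"].mean(), "real_sd": per_subj["real"].std(ddof=1),
             "pred_mean": per_subj["pred"].mean(), "pred_sd": per_subj["pred"].std(ddof=1),
             "p_value": p, "cohens_d": d,
             "rmse_mean": per_subj["rmse"].mean(), "rmse_sd": per_subj["rmse"].std(ddof=1),
             "n_subjects": len(per_subj)}
        )
    return pd.DataFrame(rows)


def run_experiment(
    trials: list[TrialRecord],
    combos: list[str] | None = None,
    grid: np.ndarray = DEFAULT_GRID,
    explained_variance: float = 0.99,
) -> dict[str, pd.DataFrame]:
    """Full LOSO experiment over the requested microphone combinations.

    Returns a dict of DataFrames: ``loso`` (per trial, per combo, with
    curves), ``subjects`` (per-runner quality means), ``style`` (accuracy
    table), ``variables`` (real-vs-pred comparison for the combo listed
    first), and ``anova`` (repeated-measures F/p across combos for r, RMSE
    and rRMSE, when more than one combo is run).
    """
    combos = combos or list(MIC_COMBINATIONS)
    unknown = set(combos) - set(MIC_COMBINATIONS)
    if unknown:
        raise ValueError(f"unknown combinations: {sorted(unknown)}")
    loso = pd.concat(
        [loso_evaluate(trials, c, grid=grid, explained_variance=explained_variance) for c in combos],
        ignore_index=True,
    )
    out: dict[str, pd.DataFrame] = {
        "loso": loso,
        "subjects": subject_summary(loso),
        "style": style_table(loso, grid),
        "variables": variable_comparison(loso[loso["combo"] == combos[0]], grid),
    }
    if len(combos) >= 2:
        subj = out["subjects"]
        anova_rows = []
        for metric in ("pearson_r", "rmse_xbw", "rrmse_pct"):
            wide = subj.pivot(index="subject_id", columns="combo", values=metric)
            if wide.notna().all().all():
                f, p = rm_anova(wide.to_numpy())
                anova_rows.append({"metric": metric, "F": f, "p_value": p,
                                   "n_subjects": len(wide), "n_conditions": wide.shape[1]})
        out["anova"] = pd.DataFrame(anova_rows)
    return out
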