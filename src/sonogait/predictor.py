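"""Conditional-likelihood prediction of vGRF coefficients from sound.

The predictor treats the stacked vector

    z = [ envelope Fourier coefficients (per microphone) |
          body mass, running speed, stance time |
          vGRF Fourier coefficients ]

as a draw from a multivariate Gaussian estimated on training trials. The
joint vectors are standardized per dimension, mean-centered and rotated into
their principal-component basis; components are retained up to a cumulative
explained-variance threshold (99% by default). A query fixes the predictor
block (sound coefficients + the three scalars) and asks for the target block
(vGRF coefficients) that maximizes the Gaussian likelihood — a convex
quadratic program

    minimize    c' diag(1/lambda) c
    subject to  W_p' c = x_p - mu_p

over the component scores ``c``, where ``W_p`` is the predictor part of the
PCA basis. The KKT system of this equality-constrained QP has the closed-form
solution ``c = Lambda W_p (W_p' Lambda W_p)^-1 (x_p - mu_p)``, which equals
the Gaussian conditional mean whenever the implied predictor covariance is
full rank; a small Tikhonov term guards the rank-deficient case.

Validation is leave-one-subject-out (LOSO): each subject's trials are
predicted by a model fitted on all other subjects, so no target information
from the held-out subject can leak into training. Nine microphone
combinations are supported, from single microphones to all four at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fourier import FourierCoefficients, eval_fourier
from .signal_processing import MicId, StanceCurve
from .stats import curve_similarity

__all__ = [
    "TrialRecord",
    "MicCombination",
    "MIC_COMBINATIONS",
    "ConditionalModel",
    "assemble_predictor_vector",
    "fit_model",
    "fit_joint_gaussian",
    "predict",
    "predict_curve",
    "loso_evaluate",
    "DEFAULT_GRID",
]

log = logging.getLogger(__name__)

#: prediction grid: 101 points over 0-100% of stance
DEFAULT_GRID = np.linspace(0.0, 1.0, 101)

_VARIANCE_FLOOR = 1e-12
_TIKHONOV = 1e-8


@dataclass(frozen=True)
class TrialRecord:
    """One footstep: per-microphone envelope coefficients plus vGRF target.

    ``grf_coeffs`` are on the body-weight (xBW) scale and were fitted over
    the trial's stance time.
    """

    subject_id: str
    trial_id: str
    mass_kg: float
    speed_mps: float
    stance_time_s: float
    envelope_coeffs: dict[MicId, FourierCoefficients]
    grf_coeffs: FourierCoefficients
    fca_deg: float | None = None

    def __post_init__(self) -> None:
        if min(self.mass_kg, self.speed_mps, self.stance_time_s) <= 0:
            raise ValueError("mass, speed and stance time must be positive")
        missing = [m for m in MicId if m not in self.envelope_coeffs]
        if missing:
            raise ValueError(f"missing microphone coefficients: {missing}")
        if abs(self.grf_coeffs.duration_s - self.stance_time_s) > 1e-9:
            raise ValueError("grf_coeffs duration must equal the stance time")


@dataclass(frozen=True)
class MicCombination:
    """A named predictor set of microphones."""

    name: str
    members: tuple[MicId, ...]


def _combos() -> dict[str, MicCombination]:
    m1, m2, m3, m4 = MicId.MIC1, MicId.MIC2, MicId.MIC3, MicId.MIC4
    sets = {
        "Mic1": (m1,),
        "Mic2": (m2,),
        "Mic3": (m3,),
        "Mic4": (m4,),
        "Mic12": (m1, m2),   # medial
        "Mic14": (m1, m4),   # posterior
        "Mic23": (m2, m3),   # anterior
        "Mic34": (m3, m4),   # lateral
        "Mic1234": (m1, m2, m3, m4),
    }
    return {name: MicCombination(name, members) for name, members in sets.items()}


#: the nine supported microphone combinations
MIC_COMBINATIONS: dict[str, MicCombination] = _combos()


@dataclass(frozen=True)
class ConditionalModel:
    """Joint Gaussian over [predictors | targets] in a PCA basis.

    ``basis`` holds retained principal axes as rows (components x joint dim),
    orthonormal; ``variances`` are the matching per-component variances in
    non-increasing order. ``scale`` holds the per-dimension standardization
    factors applied before PCA.
    """

    mean: np.ndarray
    scale: np.ndarray
    basis: np.ndarray
    variances: np.ndarray
    predictor_len: int
    target_len: int
    n_harmonics: int
    combo: str
    method: str = "subspace"

    def __post_init__(self) -> None:
        dim = self.predictor_len + self.target_len
        if self.mean.shape != (dim,) or self.scale.shape != (dim,):
            raise ValueError("mean/scale length must equal joint dimension")
        if self.basis.shape[1] != dim:
            raise ValueError("basis column count must equal joint dimension")
        if np.any(self.variances < 0) or np.any(np.diff(self.variances) > 1e-9):
            raise ValueError("variances must be non-negative and non-increasing")
        gram = self.basis @ self.basis.T
        if not np.allclose(gram, np.eye(len(self.variances)), atol=1e-8):
            raise ValueError("basis rows must be orthonormal")

    @property
    def n_components(self) -> int:
        return len(self.variances)


def assemble_predictor_vector(trial: TrialRecord, combo: MicCombination) -> np.ndarray:
    """Concatenate member-mic coefficient vectors and the three scalars.

    Layout: each member microphone's ``(2K+1)`` coefficients in combination
    order, then ``[mass_kg, speed_mps, stance_time_s]``.
    """
    parts = []
    for mic in combo.members:
        if mic not in trial.envelope_coeffs:
            raise KeyError(f"trial {trial.trial_id} lacks coefficients for {mic}")
        parts.append(trial.envelope_coeffs[mic].to_vector())
    parts.append(np.array([trial.mass_kg, trial.speed_mps, trial.stance_time_s]))
    return np.concatenate(parts)


def _joint_matrix(trials: list[TrialRecord], combo: MicCombination) -> tuple[np.ndarray, int, int]:
    rows = [np.concatenate([assemble_predictor_vector(t, combo), t.grf_coeffs.to_vector()]) for t in trials]
    X = np.vstack(rows)
    target_len = len(trials[0].grf_coeffs.to_vector())
    return X, X.shape[1] - target_len, target_len


def fit_model(
    trials: list[TrialRecord],
    combo: MicCombination | str,
    explained_variance: float = 0.99,
    method: str = "subspace",
) -> ConditionalModel:
    """Fit the joint Gaussian/PCA model on training trials.

    Joint vectors are standardized per dimension (variance floor guards
    constant dimensions), centered, and decomposed by SVD; principal axes
    are retained up to ``explained_variance`` cumulative fraction (at least
    one). ``method`` selects how :func:`predict` conditions: ``"subspace"``
    (QP over retained component scores, the default) or ``"gaussian"``
    (conditional mean of the reconstructed low-rank covariance).
    """
    if isinstance(combo, str):
        combo = MIC_COMBINATIONS[combo]
    if len(trials) < 2:
        raise ValueError("need at least 2 training trials")
    if len({t.subject_id for t in trials}) < 2:
        # legal (a two-subject LOSO fold trains on one runner) but the model
        # then carries no between-subject variation
        log.warning("fitting on trials from a single subject")
    X, p_len, t_len = _joint_matrix(trials, combo)
    model = fit_joint_gaussian(X, p_len, explained_variance=explained_variance, method=method)
    return ConditionalModel(
        mean=model.mean,
        scale=model.scale,
        basis=model.basis,
        variances=model.variances,
        predictor_len=p_len,
        target_len=t_len,
        n_harmonics=trials[0].grf_coeffs.n_harmonics,
        combo=combo.name,
        method=method,
    )


def fit_joint_gaussian(
    X: np.ndarray,
    predictor_len: int,
    explained_variance: float = 0.99,
    method: str = "subspace",
) -> ConditionalModel:
    """Fit the standardized-PCA Gaussian on raw joint row vectors.

    The workhorse behind :func:`fit_model`, exposed for models over arbitrary
    [predictor | target] vectors (toy problems, cross-checks).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D sample matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite joint vectors")
    if not 0 < predictor_len < X.shape[1]:
        raise ValueError("predictor_len must split the joint dimension")
    mean = X.mean(axis=0)
    scale = np.sqrt(np.maximum(X.var(axis=0), _VARIANCE_FLOOR))
    Z = (X - mean) / scale
    # SVD of the centered, standardized data: rows of Vt are principal axes
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    variances = s**2 / max(X.shape[0] - 1, 1)
    total = variances.sum()
    if total <= 0:
        keep = 1
    else:
        frac = np.cumsum(variances) / total
        keep = int(np.searchsorted(frac, explained_variance - 1e-12) + 1)
        keep = min(keep, len(variances))
    return ConditionalModel(
        mean=mean,
        scale=scale,
        basis=vt[:keep],
        variances=variances[:keep],
        predictor_len=predictor_len,
        target_len=X.shape[1] - predictor_len,
        n_harmonics=0,
        combo="",
        method=method,
    )


def predict(model: ConditionalModel, predictor_vector: np.ndarray) -> np.ndarray:
    """Most likely target block given the predictor block.

    Solves the maximum-conditional-likelihood QP in the model's component
    space (see module docstring). With a full-rank predictor covariance this
    is exactly the Gaussian conditional mean
    ``mu_t + Sigma_tp Sigma_pp^-1 (x - mu_p)``.
    """
    x = np.asarray(predictor_vector, dtype=float)
    if x.shape != (model.predictor_len,):
        raise ValueError(f"predictor vector must have length {model.predictor_len}, got {x.shape}")
    p = model.predictor_len
    b = (x - model.mean[:p]) / model.scale[:p]
    w_p = model.basis[:, :p]          # (n_comp, p)
    w_t = model.basis[:, p:]          # (n_comp, t)
    lam = model.variances
    if model.method == "subspace":
        # KKT solution of: min c' diag(1/lam) c  s.t.  w_p' c = b.
        # Substituting c = sqrt(lam) * d turns the objective into ||d||^2 and
        # the constraint into M d = b with M = w_p' sqrt(Lambda); the min-norm
        # least-squares d (SVD solve) satisfies the constraints exactly when
        # they are feasible (enough components) and in least squares when the
        # retained subspace cannot reach the observed predictor exactly.
        M = w_p.T * np.sqrt(lam)      # p x n_comp
        d, *_ = np.linalg.lstsq(M, b, rcond=None)
        c = np.sqrt(lam) * d
        y_std = w_t.T @ c
    elif model.method == "gaussian":
        # conditional mean under the reconstructed low-rank covariance
        sigma_pp = (w_p.T * lam) @ w_p + _TIKHONOV * np.eye(p)
        sigma_tp = (w_t.T * lam) @ w_p
        y_std = sigma_tp @ np.linalg.solve(sigma_pp, b)
    else:
        raise ValueError(f"unknown method {model.method!r}")
    return model.mean[p:] + y_std * model.scale[p:]


def predict_curve(
    model: ConditionalModel,
    trial: TrialRecord,
    combo: MicCombination | str | None = None,
    grid: np.ndarray = DEFAULT_GRID,
) -> StanceCurve:
    """Predict a trial's vGRF curve (xBW) on a normalized stance grid.

    The predicted coefficient vector is unflattened with the trial's measured
    stance time as duration and evaluated on ``grid``.
    """
    if combo is None:
        combo = MIC_COMBINATIONS[model.combo]
    elif isinstance(combo, str):
        combo = MIC_COMBINATIONS[combo]
    y = predict(model, assemble_predictor_vector(trial, combo))
    coeffs = FourierCoefficients.from_vector(y, duration_s=trial.stance_time_s)
    values = eval_fourier(coeffs, grid)
    return StanceCurve(values=values, times=grid * trial.stance_time_s, normalized=True)


def loso_evaluate(
    trials: list[TrialRecord],
    combo: MicCombination | str,
    grid: np.ndarray = DEFAULT_GRID,
    explained_variance: float = 0.99,
    method: str = "subspace",
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation for one microphone combination.

    For each subject a model is fitted on every *other* subject's trials and
    each held-out trial's curve is predicted; per-trial quality metrics
    (Pearson r, RMSE, rRMSE against the reconstructed real curve on the same
    grid) are returned in a long DataFrame with one row per trial, columns
    ``subject_id, trial_id, combo, pearson_r, rmse_xbw, rrmse_pct`` plus the
    real/predicted curves as object columns.
    """
    if isinstance(combo, str):
        combo = MIC_COMBINATIONS[combo]
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    rows = []
    for held_out in subjects:
        train = [t for t in trials if t.subject_id != held_out]
        test = [t for t in trials if t.subject_id == held_out]
        model = fit_model(train, combo, explained_variance=explained_variance, method=method)
        for t in test:
            real = eval_fourier(t.grf_coeffs, grid)
            pred = predict_curve(model, t, combo, grid)
            q = curve_similarity(real, pred.values)
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "trial_id": t.trial_id,
                    "combo": combo.name,
                    "pearson_r": q.pearson_r,
                    "rmse_xbw": q.rmse_xbw,
                    "rrmse_pct": q.rrmse_pct,
                    "real_curve": real,
                    "pred_curve": pred.values,
                    "stance_time_s": t.stance_time_s,
                }
            )
    return pd.DataFrame(rows)
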