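"""File formats: WAV audio, force CSVs, per-stance curves, coefficient tables.

Layouts
-------
* audio: standard WAV (PCM16/32 or float), one file per microphone
  (``<subject>_<mic>.wav``) or one 4-channel file with a channel->mic map;
* force: CSV with header ``time_s,fz_n`` at a fixed rate (Newtons);
* per-stance curves: CSV ``time_s,value`` plus a JSON sidecar carrying
  subject/mic/window metadata;
* trial coefficient tables: one wide CSV row per footstep holding the
  scalars and the Fourier coefficient vectors of the vGRF and all four
  envelopes — the interchange format between preprocessing and the
  predictor;
* synthetic raw cohorts: the generator's trials rendered back to WAV + force
  CSV so the full preprocessing chain can be exercised end to end. The audio
  is an amplitude-modulated 1 kHz tone whose linear envelope reproduces the
  generated envelope (a full-wave-rectified unit sine has mean 2/pi, so the
  carrier is scaled by pi/2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .fourier import FourierCoefficients
from .predictor import TrialRecord
from .signal_processing import EnvelopeCurve, ForceRecording, MicId, SoundRecording, StanceCurve
from .synthetic import CohortSpec, generate_cohort, generate_envelopes, generate_vgrf
from . import synthetic as _syn
from .signal_processing import FootStrike

__all__ = [
    "read_wav",
    "write_wav",
    "read_force_csv",
    "write_force_csv",
    "write_stance_csv",
    "read_stance_csv",
    "trials_to_frame",
    "frame_to_trials",
    "write_raw_cohort",
    "config_hash",
]

#: gap of silence / zero force inserted between consecutive stances (s)
FLIGHT_GAP_S = 0.45
_CARRIER_HZ = 1000.0


def read_wav(path: str | Path, mic_id: MicId, channel: int = 0) -> SoundRecording:
    """Load one microphone channel from a WAV file as linear amplitude.

    Integer PCM is rescaled to [-1, 1]; multichannel files are indexed by
    ``channel``.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return SoundRecording(samples=data, rate=float(rate), mic_id=mic_id)


def write_wav(path: str | Path, samples: np.ndarray, rate: float) -> None:
    wavfile.write(str(path), int(rate), np.asarray(samples, dtype=np.float32))


def read_force_csv(path: str | Path, subject_id: str = "", rate: float | None = None) -> ForceRecording:
    """Load a ``time_s,fz_n`` CSV; the rate is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    if not {"time_s", "fz_n"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, fz_n, got {list(df.columns)}")
    if rate is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        rate = float(round(1.0 / dt))
    return ForceRecording(samples=df["fz_n"].to_numpy(float), rate=rate, subject_id=subject_id)


def write_force_csv(path: str | Path, samples: np.ndarray, rate: float) -> None:
    t = np.arange(len(samples)) / rate
    pd.DataFrame({"time_s": t, "fz_n": samples}).to_csv(path, index=False, float_format="%.6f")


def write_stance_csv(path: str | Path, curve: StanceCurve | EnvelopeCurve, meta: dict | None = None) -> None:
    """Write one per-stance curve as ``time_s,value`` with a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": curve.times, "value": curve.values}).to_csv(path, index=False, float_format="%.8f")
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_stance_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df["time_s"].to_numpy(float), df["value"].to_numpy(float), meta


# -- trial coefficient tables --------------------------------------------------

def _coef_columns(prefix: str, k: int) -> list[str]:
    return [f"{prefix}_a0"] + [f"{prefix}_a{i}" for i in range(1, k + 1)] + [f"{prefix}_b{i}" for i in range(1, k + 1)]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to one wide CSV-ready row per footstep."""
    if not trials:
        return pd.DataFrame()
    k = trials[0].grf_coeffs.n_harmonics
    rows = []
    for t in trials:
        row: dict = {
            "subject_id": t.subject_id,
            "trial_id": t.trial_id,
            "mass_kg": t.mass_kg,
            "speed_mps": t.speed_mps,
            "stance_time_s": t.stance_time_s,
            "fca_deg": t.fca_deg if t.fca_deg is not None else np.nan,
        }
        row.update(dict(zip(_coef_columns("grf", k), t.grf_coeffs.to_vector())))
        for mic in MicId:
            row.update(dict(zip(_coef_columns(mic.value.lower(), k), t.envelope_coeffs[mic].to_vector())))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`."""
    k = max(int(c.split("_a")[-1]) for c in df.columns if c.startswith("grf_a") and c != "grf_a0")
    trials = []
    for _, row in df.iterrows():
        dur = float(row["stance_time_s"])
        grf = FourierCoefficients.from_vector(row[_coef_columns("grf", k)].to_numpy(float), duration_s=dur)
        envs = {
            mic: FourierCoefficients.from_vector(
                row[_coef_columns(mic.value.lower(), k)].to_numpy(float), duration_s=dur
            )
            for mic in MicId
        }
        fca = float(row["fca_deg"])
        trials.append(
            TrialRecord(
                subject_id=str(row["subject_id"]),
                trial_id=str(row["trial_id"]),
                mass_kg=float(row["mass_kg"]),
                speed_mps=float(row["speed_mps"]),
                stance_time_s=dur,
                envelope_coeffs=envs,
                grf_coeffs=grf,
                fca_deg=None if np.isnan(fca) else fca,
            )
        )
    return trials


# -- raw synthetic cohorts -----------------------------------------------------

def write_raw_cohort(
    out_dir: str | Path,
    spec: CohortSpec | None = None,
    seed: int | None = None,
    sound_rate_hz: float = 20_000.0,
) -> pd.DataFrame:
    """Render a synthetic cohort to raw WAV + force-CSV files on disk.

    Per subject: ``<id>_force.csv`` (1000 Hz Newtons, stances separated by
    zero-force flight gaps) and four ``<id>_Mic<j>.wav`` files (float WAV at
    ``sound_rate_hz``) whose envelopes reproduce the generated ones, sharing
    the force trace's time zero. Also writes ``subjects.csv`` (scalars per
    subject) and ``ground_truth.csv``; returns the ground-truth table.
    """
    spec = spec or CohortSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    g = 9.81
    n_rear = int(round(spec.rearfoot_fraction * spec.n_subjects))
    styles = [FootStrike.REARFOOT] * n_rear
    others = spec.n_subjects - n_rear
    n_mid = int(round(others * 21.0 / 30.0))
    styles += [FootStrike.MIDFOOT] * n_mid + [FootStrike.FOREFOOT] * (others - n_mid)
    rng.shuffle(styles)

    gap_f = int(FLIGHT_GAP_S * spec.force_rate_hz)
    gap_s = int(FLIGHT_GAP_S * sound_rate_hz)
    subj_rows, truth_rows = [], []
    for idx, style in enumerate(styles, start=1):
        subj = _syn._draw_subject(rng, spec, idx, style)
        bw_n = subj.mass_kg * g
        n_trials = max(int(round(rng.normal(spec.cycles_mean, spec.cycles_sd))), 3)
        force_parts = [np.zeros(gap_f)]
        sound_parts = {mic: [np.zeros(gap_s)] for mic in MicId}
        for j in range(n_trials):
            t_imp = subj.t_impact_pct + float(rng.normal(0.0, spec.trial_jitter_pct))
            t_act = max(subj.t_active_pct + float(rng.normal(0.0, spec.trial_jitter_pct)), t_imp + 10.0)
            params = dict(
                impact_peak_xbw=subj.impact_peak_xbw * float(rng.normal(1.0, spec.trial_jitter_frac)),
                t_impact_pct=t_imp,
                active_peak_xbw=subj.active_peak_xbw * float(rng.normal(1.0, spec.trial_jitter_frac)),
                t_active_pct=t_act,
            )
            stance_t = subj.stance_time_s * float(rng.normal(1.0, 0.02))
            vgrf = generate_vgrf(style, stance_time_s=stance_t, force_rate_hz=spec.force_rate_hz, **params)
            force_parts += [vgrf.values * bw_n, np.zeros(gap_f)]
            gains = np.asarray(spec.mic_gains) * subj.gain_multipliers
            envs = generate_envelopes(vgrf, gains, spec.coupling_w1, spec.coupling_w2, spec.noise_sigma, rng=rng)
            n_snd = int(round(stance_t * sound_rate_hz))
            t_snd = np.arange(n_snd) / sound_rate_hz
            for env in envs:
                target = np.interp(t_snd, env.times, env.values)
                carrier = np.sin(2 * np.pi * _CARRIER_HZ * t_snd)
                sound_parts[env.mic_id] += [(np.pi / 2.0) * target * carrier, np.zeros(gap_s)]
            truth_rows.append(
                {"subject_id": subj.subject_id, "trial_id": f"{subj.subject_id}_T{j:03d}",
                 "style": style.value, "stance_time_s": stance_t, **params}
            )
        write_force_csv(out / f"{subj.subject_id}_force.csv", np.concatenate(force_parts), spec.force_rate_hz)
        for mic in MicId:
            write_wav(out / f"{subj.subject_id}_{mic.value}.wav", np.concatenate(sound_parts[mic]), sound_rate_hz)
        subj_rows.append(
            {"subject_id": subj.subject_id, "mass_kg": subj.mass_kg, "speed_mps": subj.speed_mps,
             "fca_deg": subj.fca_deg, "style": style.value}
        )
    pd.DataFrame(subj_rows).to_csv(out / "subjects.csv", index=False, float_format="%.6f")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    return truth


def config_hash(obj) -> str:
    """Stable short hash of a dataclass/dict config, for manifests."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=lambda o: list(o) if isinstance(o, (np.ndarray, tuple)) else str(o))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
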