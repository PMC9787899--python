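"""Force and sound preprocessing: filters, stance segmentation, envelopes.

The processing chain mirrors standard overground-running instrumentation:

* vertical force from a floor-embedded plate at 1000 Hz, low-pass filtered
  (4th-order Butterworth, 60 Hz) and segmented into stance phases wherever
  the force exceeds 20 N;
* microphone audio at 44.1 kHz, resampled to 20 kHz, band-pass filtered
  (1st-order Butterworth, 5 Hz–20 kHz), full-wave rectified and low-pass
  filtered at 200 Hz into a linear envelope, then cropped to each stance
  window using the force-plate events (the two streams share a trigger).

All low-pass stages are applied forward–backward (zero phase) so event
timing is not lagged. Foot-strike style from the foot contact angle (FCA)
uses the conventional thresholds: rearfoot >= 8 deg, forefoot <= -1.6 deg,
midfoot in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "MicId",
    "FootStrike",
    "ProcessingConfig",
    "ForceRecording",
    "SoundRecording",
    "StanceCurve",
    "EnvelopeCurve",
    "filter_force",
    "segment_stances",
    "normalize_stance",
    "compute_envelope",
    "segment_envelope",
    "classify_fca",
]

log = logging.getLogger(__name__)


class MicId(str, Enum):
    """The four shotgun microphones around the force plate.

    Mic1 posterior-left, Mic2 anterior-left, Mic3 anterior-right,
    Mic4 posterior-right.
    """

    MIC1 = "Mic1"
    MIC2 = "Mic2"
    MIC3 = "Mic3"
    MIC4 = "Mic4"


class FootStrike(str, Enum):
    REARFOOT = "rearfoot"
    MIDFOOT = "midfoot"
    FOREFOOT = "forefoot"
    #: merged class used when style is read off the vGRF alone
    FOREFOOT_MIDFOOT = "forefoot_midfoot"


@dataclass(frozen=True)
class ProcessingConfig:
    """Filter cutoffs, thresholds and class boundaries for preprocessing.

    Defaults are the conventional values for treadmill/overground running
    kinetics with synchronized audio. ``band_edges_hz`` has its upper edge at
    the Nyquist frequency of the 20 kHz working rate, so the band-pass reduces
    to a first-order high-pass at 5 Hz (logged when exercised).
    """

    force_lowpass_hz: float = 60.0           # 4th-order Butterworth, zero phase
    force_filter_order: int = 4
    stance_threshold_n: float = 20.0         # strictly "above 20 N"
    min_stance_s: float = 0.08               # discard bounces / noise blips
    sound_resample_hz: float = 20_000.0
    band_edges_hz: tuple[float, float] = (5.0, 20_000.0)  # 1st-order Butterworth
    envelope_lowpass_hz: float = 200.0
    envelope_lowpass_order: int = 4
    fca_rearfoot_deg: float = 8.0
    fca_forefoot_deg: float = -1.6
    apply_db_conversion: bool = False        # envelopes computed on linear amplitude

    def __post_init__(self) -> None:
        if self.force_lowpass_hz <= 0 or self.envelope_lowpass_hz <= 0 or self.sound_resample_hz <= 0:
            raise ValueError("all frequencies must be positive")
        lo, hi = self.band_edges_hz
        if lo <= 0 or lo >= hi:
            raise ValueError(f"band edges must satisfy 0 < low < high, got {self.band_edges_hz}")
        if self.stance_threshold_n <= 0:
            raise ValueError("stance threshold must be positive")
        if self.fca_forefoot_deg >= self.fca_rearfoot_deg:
            raise ValueError("forefoot boundary must lie below rearfoot boundary")


@dataclass(frozen=True)
class ForceRecording:
    """Vertical force channel in Newtons at a fixed sampling rate."""

    samples: np.ndarray
    rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force samples must be finite")


@dataclass(frozen=True)
class SoundRecording:
    """One microphone channel in linear amplitude units."""

    samples: np.ndarray
    rate: float
    mic_id: MicId

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "mic_id", MicId(self.mic_id))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sound samples must be finite")


@dataclass(frozen=True)
class StanceCurve:
    """Vertical force over one stance phase.

    ``values`` are Newtons when ``normalized`` is False, otherwise multiples
    of body weight (xBW). ``times`` start at 0 at initial contact.
    """

    values: np.ndarray
    times: np.ndarray
    body_weight_n: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal shape")
        if len(self.times) >= 2:
            if abs(self.times[0]) > 1e-12:
                raise ValueError("stance times must start at 0")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("stance times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class EnvelopeCurve:
    """Sound envelope for one microphone over one stance window."""

    values: np.ndarray
    times: np.ndarray
    mic_id: MicId

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "mic_id", MicId(self.mic_id))
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal shape")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


def filter_force(rec: ForceRecording, cfg: ProcessingConfig = ProcessingConfig()) -> ForceRecording:
    """Zero-phase low-pass Butterworth filter of the vertical force.

    Raises ``ValueError`` when the sampling rate does not exceed twice the
    cutoff (the filter design would alias).
    """
    if rec.rate <= 2.0 * cfg.force_lowpass_hz:
        raise ValueError(
            f"sampling rate {rec.rate} Hz must exceed twice the {cfg.force_lowpass_hz} Hz cutoff"
        )
    sos = sps.butter(cfg.force_filter_order, cfg.force_lowpass_hz, btype="low", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def segment_stances(rec: ForceRecording, cfg: ProcessingConfig = ProcessingConfig()) -> list[tuple[int, int]]:
    """Find stance phases as maximal runs of force strictly above 20 N.

    Returns ``(start, end)`` index pairs with Python half-open convention
    ``samples[start:end] > threshold``; runs shorter than ``min_stance_s``
    are discarded as bounces. An all-quiet recording yields an empty list.
    """
    above = rec.samples > cfg.stance_threshold_n
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    min_len = int(np.ceil(cfg.min_stance_s * rec.rate))
    intervals = [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]
    if len(intervals) < len(starts):
        log.info("discarded %d sub-%.0f-ms force bursts", len(starts) - len(intervals), cfg.min_stance_s * 1e3)
    return intervals


def stance_curve_from_interval(rec: ForceRecording, interval: tuple[int, int]) -> StanceCurve:
    """Extract a stance window as a curve with time re-based to contact."""
    s, e = interval
    values = rec.samples[s:e]
    times = np.arange(e - s) / rec.rate
    return StanceCurve(values=values, times=times)


def normalize_stance(curve: StanceCurve, body_weight_n: float) -> StanceCurve:
    """Express the stance force in multiples of body weight (xBW)."""
    if body_weight_n <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_n}")
    if curve.normalized:
        raise ValueError("curve is already body-weight normalized")
    return replace(curve, values=curve.values / body_weight_n, body_weight_n=body_weight_n, normalized=True)


def compute_envelope(rec: SoundRecording, cfg: ProcessingConfig = ProcessingConfig()) -> np.ndarray:
    """Linear envelope of a microphone signal at the 20 kHz working rate.

    Chain: polyphase resample to ``sound_resample_hz`` -> first-order
    Butterworth band-pass -> full-wave rectification -> zero-phase low-pass
    at ``envelope_lowpass_hz``. When the upper band edge reaches Nyquist the
    band-pass degenerates to a high-pass at the lower edge.
    """
    if rec.rate < 2.0 * cfg.envelope_lowpass_hz:
        raise ValueError("sampling rate too low for the envelope low-pass")
    x = rec.samples
    if x.size == 0:
        return np.empty(0)
    if rec.rate != cfg.sound_resample_hz:
        ratio = Fraction(cfg.sound_resample_hz / rec.rate).limit_denominator(1000)
        x = sps.resample_poly(x, ratio.numerator, ratio.denominator)
    fs = cfg.sound_resample_hz
    lo, hi = cfg.band_edges_hz
    nyq = fs / 2.0
    if hi >= nyq:
        log.info("band-pass upper edge %.0f Hz >= Nyquist %.0f Hz: applying high-pass at %.0f Hz only", hi, nyq, lo)
        sos = sps.butter(1, lo, btype="high", fs=fs, output="sos")
    else:
        sos = sps.butter(1, (lo, hi), btype="band", fs=fs, output="sos")
    x = sps.sosfilt(sos, x)
    rectified = np.abs(x)
    sos_env = sps.butter(cfg.envelope_lowpass_order, cfg.envelope_lowpass_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos_env, rectified)


def segment_envelope(
    envelope: np.ndarray,
    stance: tuple[int, int],
    force_rate: float,
    sound_rate: float,
    mic_id: MicId,
) -> EnvelopeCurve:
    """Crop a full-length envelope to one stance window.

    The force and sound streams share a common start trigger, so force-sample
    indices map to envelope indices by the rate ratio. Times are re-based to
    0 at initial contact.
    """
    s_f, e_f = stance
    ratio = sound_rate / force_rate
    s = int(round(s_f * ratio))
    e = int(round(e_f * ratio))
    if s < 0 or e > len(envelope) or s >= e:
        raise ValueError(
            f"stance window [{s_f}, {e_f}) at {force_rate} Hz maps to [{s}, {e}) "
            f"outside the {len(envelope)}-sample envelope"
        )
    values = envelope[s:e]
    times = np.arange(e - s) / sound_rate
    return EnvelopeCurve(values=values, times=times, mic_id=mic_id)


def classify_fca(fca_deg: float, cfg: ProcessingConfig = ProcessingConfig()) -> FootStrike:
    """Classify foot strike from the foot contact angle (degrees).

    Rearfoot when ``FCA >= 8``; forefoot when ``FCA <= -1.6``; midfoot in the
    open interval between. Both boundaries are closed toward the outer class.
    """
    if not np.isfinite(fca_deg):
        raise ValueError(f"FCA must be finite, got {fca_deg}")
    if fca_deg >= cfg.fca_rearfoot_deg:
        return FootStrike.REARFOOT
    if fca_deg <= cfg.fca_forefoot_deg:
        return FootStrike.FOREFOOT
    return FootStrike.MIDFOOT
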