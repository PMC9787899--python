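"""Biomechanical variables extracted from vGRF stance curves.

Implements the standard running-kinetics feature set on body-weight
normalized stance curves:

* impact peak — largest local maximum within the first 50 ms of contact,
  when one exists;
* deflection point — surrogate impact-peak location for curves without a
  local maximum, found by scanning 10–100 ms for the sharpest concave turn
  between two sequential 15 ms chords of the curve;
* active peak — global maximum and its timing in percent stance;
* loading rates LR-1 (average slope to the impact peak), LR-2 (secant slope
  between the 20% and 80% crossings of the impact-peak force) and LR-3
  (least-squares slope over the first 50 ms), all in xBW/s;
* vertical impulse — area under the curve, reported both in xBW*s and
  integrated over percent-stance units;
* binary foot-strike style (rearfoot vs forefoot/midfoot) from the presence
  of a prominent impact peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_processing import FootStrike, StanceCurve

__all__ = [
    "BiomechVariables",
    "find_impact_peak",
    "find_deflection_point",
    "active_peak",
    "loading_rates",
    "vertical_impulse",
    "classify_style_from_vgrf",
    "style_accuracy",
    "extract_variables",
]

log = logging.getLogger(__name__)

#: impact peaks are searched within the first 50 ms of stance
IMPACT_WINDOW_S = 0.050
#: topographic prominence (xBW) above which a local max counts as an impact peak
DEFAULT_PROMINENCE_XBW = 0.05
#: deflection-scan chord length and candidate window
DEFLECTION_CHORD_S = 0.015
DEFLECTION_WINDOW_S = (0.010, 0.100)
DEFLECTION_STEP_S = 0.001
#: time axis scaling (s -> s*100) used when measuring turning angles, so a
#: 15 ms chord and typical xBW force changes have comparable magnitudes
DEFLECTION_TIME_SCALE = 100.0


@dataclass(frozen=True)
class BiomechVariables:
    """One row of the per-stance variables table."""

    impact_peak_xbw: float | None
    t_impact_peak_pct: float | None
    impact_peak_found: bool
    active_peak_xbw: float
    t_active_peak_pct: float
    lr1_xbw_s: float | None
    lr2_xbw_s: float | None
    lr3_xbw_s: float
    impulse_xbw_s: float
    impulse_xbw_pct: float
    style_vgrf: FootStrike


def _require_normalized(curve: StanceCurve) -> None:
    if not curve.normalized:
        raise ValueError("curve must be body-weight normalized (xBW)")


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateau maxima use the plateau start)."""
    peaks, _ = sps.find_peaks(values, plateau_size=1)
    return peaks


def find_impact_peak(curve: StanceCurve, window_s: float = IMPACT_WINDOW_S) -> tuple[float, float] | None:
    """Largest local maximum of the vGRF within the first 50 ms, or None.

    Returns ``(value_xbw, time_s)``; a curve that rises monotonically through
    the window has no impact peak.
    """
    _require_normalized(curve)
    if curve.duration_s <= window_s:
        raise ValueError(f"stance shorter than the {window_s * 1e3:.0f} ms impact window")
    peaks = _local_maxima(curve.values)
    peaks = peaks[curve.times[peaks] <= window_s + 1e-12]
    if peaks.size == 0:
        return None
    best = peaks[np.argmax(curve.values[peaks])]
    return float(curve.values[best]), float(curve.times[best])


def find_deflection_point(
    curve: StanceCurve,
    chord_s: float = DEFLECTION_CHORD_S,
    window_s: tuple[float, float] = DEFLECTION_WINDOW_S,
    step_s: float = DEFLECTION_STEP_S,
    time_scale: float = DEFLECTION_TIME_SCALE,
) -> float | None:
    """Onset of curve deflection: surrogate impact-peak time for peakless curves.

    For each candidate time ``t`` (1 ms grid) the signed turning angle between
    the chord from ``t - 15 ms`` to ``t`` and the chord from ``t`` to
    ``t + 15 ms`` is measured in the scaled (time*100, xBW) plane; the ``t``
    with the most negative angle (sharpest concave turn) is returned. A curve
    with no concave turn anywhere in the window returns None with a warning.
    """
    _require_normalized(curve)
    if curve.duration_s <= window_s[1] + chord_s:
        raise ValueError("stance too short for the deflection scan")
    lo = max(window_s[0], chord_s)
    hi = min(window_s[1], curve.duration_s - chord_s)
    candidates = np.arange(lo, hi + 1e-12, step_s)
    if candidates.size == 0:
        raise ValueError("deflection window is empty for this curve")

    f = lambda t: np.interp(t, curve.times, curve.values)
    angles = np.empty(candidates.size)
    for i, t in enumerate(candidates):
        u = (chord_s * time_scale, f(t) - f(t - chord_s))
        v = (chord_s * time_scale, f(t + chord_s) - f(t))
        cross = u[0] * v[1] - u[1] * v[0]
        angles[i] = np.arctan2(cross, u[0] * v[0] + u[1] * v[1])
    i_min = int(np.argmin(angles))
    if angles[i_min] >= -1e-9:
        log.warning("no concave deflection found in %s-%s ms window", *[f"{w * 1e3:.0f}" for w in window_s])
        return None
    return float(candidates[i_min])


def active_peak(curve: StanceCurve) -> tuple[float, float]:
    """Global maximum of the stance curve: ``(value_xbw, time_pct)``.

    Ties resolve to the earliest sample.
    """
    _require_normalized(curve)
    if len(curve.values) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(curve.values))
    return float(curve.values[i]), float(100.0 * curve.times[i] / curve.duration_s)


def loading_rates(
    curve: StanceCurve,
    impact_time_s: float,
    impact_value_xbw: float | None = None,
    lr3_window_s: float = IMPACT_WINDOW_S,
    lr3_method: str = "least_squares",
) -> tuple[float | None, float | None, float]:
    """Loading rates LR-1/2/3 in xBW/s given an impact location.

    ``impact_time_s`` is the impact-peak time, or the deflection-point time
    for curves without a true peak; ``impact_value_xbw`` defaults to the
    curve value at that time. LR-2 is None when the 20%/80% crossings of the
    impact force do not both occur before the impact time.
    """
    _require_normalized(curve)
    if impact_time_s <= 0:
        raise ValueError("impact time must be positive")
    f_ip = float(np.interp(impact_time_s, curve.times, curve.values)) if impact_value_xbw is None else impact_value_xbw

    lr1 = f_ip / impact_time_s

    lr2: float | None = None
    rising = curve.times <= impact_time_s + 1e-12
    t_r, v_r = curve.times[rising], curve.values[rising]
    t20 = _first_crossing(t_r, v_r, 0.2 * f_ip)
    t80 = _first_crossing(t_r, v_r, 0.8 * f_ip)
    if t20 is not None and t80 is not None and t80 > t20:
        lr2 = (0.8 - 0.2) * f_ip / (t80 - t20)

    in_window = curve.times <= lr3_window_s + 1e-12
    t_w, v_w = curve.times[in_window], curve.values[in_window]
    if lr3_method == "least_squares":
        lr3 = float(np.polyfit(t_w, v_w, 1)[0])
    elif lr3_method == "endpoint":
        lr3 = float((v_w[-1] - v_w[0]) / (t_w[-1] - t_w[0]))
    else:
        raise ValueError(f"unknown lr3_method {lr3_method!r}")
    return lr1, lr2, lr3


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """Time of the first upward crossing of ``level``, by linear interpolation."""
    above = values >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def vertical_impulse(curve: StanceCurve) -> tuple[float, float]:
    """Area under the vGRF curve.

    Returns ``(impulse_xbw_s, impulse_xbw_pct)``: the trapezoidal integral
    over seconds and over percent-stance units (the latter is the former
    scaled by ``100 / duration``). Both conventions appear in the running
    literature; neither is privileged here.
    """
    _require_normalized(curve)
    if len(curve.values) == 0:
        raise ValueError("empty curve")
    impulse_s = float(np.trapezoid(curve.values, curve.times))
    return impulse_s, impulse_s * 100.0 / curve.duration_s


def classify_style_from_vgrf(
    curve: StanceCurve,
    window_s: float = IMPACT_WINDOW_S,
    prominence_xbw: float = DEFAULT_PROMINENCE_XBW,
) -> FootStrike:
    """Binary foot-strike style read off the vGRF shape.

    Rearfoot iff the first 50 ms contain a local maximum with topographic
    prominence of at least ``prominence_xbw``; otherwise forefoot/midfoot.
    """
    _require_normalized(curve)
    peaks, props = sps.find_peaks(curve.values, prominence=prominence_xbw, plateau_size=1)
    peaks = peaks[curve.times[peaks] <= window_s + 1e-12]
    return FootStrike.REARFOOT if peaks.size else FootStrike.FOREFOOT_MIDFOOT


def style_accuracy(real_labels: list, pred_labels: list) -> float:
    """Fraction of predictions matching the reference labels."""
    if len(real_labels) != len(pred_labels):
        raise ValueError("label lists must have equal length")
    if len(real_labels) == 0:
        raise ValueError("empty label lists")
    hits = sum(r == p for r, p in zip(real_labels, pred_labels))
    return hits / len(real_labels)


def extract_variables(curve: StanceCurve) -> BiomechVariables:
    """Compute the full per-stance variables row for one curve.

    When no impact peak is identifiable the deflection point serves as the
    impact location for LR-1/LR-2 and for the reported impact time, matching
    how peakless (forefoot/midfoot) curves are handled in practice.
    """
    peak = find_impact_peak(curve)
    found = peak is not None
    if found:
        ip_val, ip_t = peak
    else:
        t_defl = find_deflection_point(curve)
        if t_defl is None:
            ip_val, ip_t = None, None
        else:
            ip_t = t_defl
            ip_val = float(np.interp(ip_t, curve.times, curve.values))

    ap_val, ap_pct = active_peak(curve)
    if ip_t is not None:
        lr1, lr2, lr3 = loading_rates(curve, ip_t, ip_val)
        ip_pct = 100.0 * ip_t / curve.duration_s
    else:
        lr1 = lr2 = None
        _, _, lr3 = loading_rates(curve, curve.duration_s / 2, 0.0)  # lr3 only needs the window
        ip_pct = None
    imp_s, imp_pct = vertical_impulse(curve)
    return BiomechVariables(
        impact_peak_xbw=ip_val,
        t_impact_peak_pct=ip_pct,
        impact_peak_found=found,
        active_peak_xbw=ap_val,
        t_active_peak_pct=ap_pct,
        lr1_xbw_s=lr1,
        lr2_xbw_s=lr2,
        lr3_xbw_s=lr3,
        impulse_xbw_s=imp_s,
        impulse_xbw_pct=imp_pct,
        style_vgrf=classify_style_from_vgrf(curve),
    )
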