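"""Truncated Fourier-series representation of stance-aligned curves.

Every curve handled by the predictor — vertical ground reaction force (vGRF)
in body weights, or a microphone sound envelope — is reduced to the
coefficients of a truncated Fourier series fitted over its own stance
duration ``T``::

    f(t) ~= a0 + sum_{k=1..K} [ a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T) ]

The default harmonic count is ``K = 15``: enough terms to preserve the sharp
impact peak of a rearfoot vGRF, which lower-order representations smooth away.
Fitting is by linear least squares on the (possibly non-uniform) sample grid,
which coincides with FFT-bin extraction on uniform grids but remains
well-defined after resampling or cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FourierCoefficients", "fit_fourier", "eval_fourier", "DEFAULT_HARMONICS"]

#: Harmonic count used for both vGRF and sound-envelope curves.
DEFAULT_HARMONICS = 15


@dataclass(frozen=True)
class FourierCoefficients:
    """Constant term plus ``K`` cosine/sine harmonic coefficients.

    Parameters
    ----------
    a0
        Constant (mean-level) term.
    a, b
        Cosine and sine coefficients, each of length ``K``.
    duration_s
        Stance duration the curve was fitted over; the coefficients describe
        shape on normalized time, and the duration is carried separately.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.ndim != 1 or self.b.ndim != 1 or len(self.a) != len(self.b):
            raise ValueError("a and b must be 1-D and of equal length")
        if len(self.a) < 1:
            raise ValueError("at least one harmonic is required")
        if not np.isfinite(self.duration_s) or self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not (np.isfinite(self.a0) and np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("coefficients must be finite")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def to_vector(self) -> np.ndarray:
        """Flatten to a length ``2K+1`` vector ordered ``a0, a1..aK, b1..bK``.

        The ordering is fixed so that coefficient vectors serialize stably and
        round-trip exactly through :meth:`from_vector`.
        """
        return np.concatenate(([self.a0], self.a, self.b))

    @classmethod
    def from_vector(cls, vec: np.ndarray, duration_s: float) -> "FourierCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.ndim != 1 or len(vec) < 3 or len(vec) % 2 == 0:
            raise ValueError(f"coefficient vector must have odd length >= 3, got {vec.shape}")
        k = (len(vec) - 1) // 2
        return cls(a0=float(vec[0]), a=vec[1 : 1 + k], b=vec[1 + k :], duration_s=duration_s)

    def term_names(self) -> list[str]:
        k = self.n_harmonics
        return ["a0"] + [f"a{i}" for i in range(1, k + 1)] + [f"b{i}" for i in range(1, k + 1)]


def _design_matrix(t_norm: np.ndarray, k: int) -> np.ndarray:
    # columns: [1, cos(2 pi t), .., cos(2 pi K t), sin(2 pi t), .., sin(2 pi K t)]
    harmonics = 2.0 * np.pi * np.arange(1, k + 1)
    phase = np.outer(t_norm, harmonics)
    return np.hstack([np.ones((len(t_norm), 1)), np.cos(phase), np.sin(phase)])


def fit_fourier(values: np.ndarray, times: np.ndarray, k: int = DEFAULT_HARMONICS) -> FourierCoefficients:
    """Least-squares fit of a ``K``-harmonic Fourier series over ``[0, T]``.

    Parameters
    ----------
    values, times
        Samples of the curve; ``times`` span ``[0, T]`` in seconds and need
        not be uniform. ``T`` is taken as ``times[-1]`` when the grid ends
        short of a full period sample.
    k
        Harmonic count; the fitted model has ``2k+1`` real coefficients.

    Raises
    ------
    ValueError
        If fewer than ``2k+1`` samples are supplied (the normal equations
        would be rank-deficient).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape or values.ndim != 1:
        raise ValueError("values and times must be 1-D arrays of equal length")
    if len(values) < 2 * k + 1:
        raise ValueError(f"need at least {2 * k + 1} samples to fit {k} harmonics, got {len(values)}")
    duration = float(times[-1] - times[0])
    if duration <= 0:
        raise ValueError("times must span a positive duration")
    t_norm = (times - times[0]) / duration
    design = _design_matrix(t_norm, k)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return FourierCoefficients(a0=float(coef[0]), a=coef[1 : 1 + k], b=coef[1 + k :], duration_s=duration)


def eval_fourier(coeffs: FourierCoefficients, grid: np.ndarray) -> np.ndarray:
    """Evaluate the series on normalized times ``grid`` in ``[0, 1]``."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return np.empty(0)
    if grid.min() < -1e-12 or grid.max() > 1 + 1e-12:
        raise ValueError("grid must lie within [0, 1]")
    design = _design_matrix(grid, coeffs.n_harmonics)
    return design @ coeffs.to_vector()
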