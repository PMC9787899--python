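import numpy as np
import pytest

from sonogait import CohortSpec, FootStrike, StanceCurve, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by predictor-level tests."""
    spec = CohortSpec(n_subjects=8, cycles_mean=12, cycles_sd=2, seed=11)
    trials, truth = generate_cohort(spec)
    return trials, truth


def make_two_bump_curve(
    impact_xbw: float = 1.5,
    t_impact_s: float = 0.034,
    active_xbw: float = 2.3,
    t_active_s: float = 0.105,
    duration_s: float = 0.25,
    rate_hz: float = 1000.0,
) -> StanceCurve:
    """Hand-built rearfoot-like curve: narrow early bump + broad active bump."""
    t = np.arange(0.0, duration_s + 1e-12, 1.0 / rate_hz)
    impact = impact_xbw * np.exp(-0.5 * ((t - t_impact_s) / 0.008) ** 2)
    active = active_xbw * np.exp(-0.5 * ((t - t_active_s) / 0.045) ** 2)
    return StanceCurve(values=np.maximum(impact, active), times=t, normalized=True)


@pytest.fixture
def two_bump_curve() -> StanceCurve:
    return make_two_bump_curve()


@pytest.fixture
def smooth_forefoot_curve() -> StanceCurve:
    """Single smooth bump, monotone through the impact window."""
    t = np.arange(0.0, 0.25 + 1e-12, 1e-3)
    values = 2.3 * np.sin(np.pi * t / 0.25) ** 2
    return StanceCurve(values=values, times=t, normalized=True)
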