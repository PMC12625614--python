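import numpy as np
import pandas as pd
import pytest

from sleeproutine import GeneratorConfig, generate_cohort
from sleeproutine.metrics import SleepEpochSeries


def series_from_intervals(intervals_per_day, epoch_minutes=5, pid="p"):
    """Build a SleepEpochSeries from per-day lists of (start_min, end_min)."""
    n_ep = 1440 // epoch_minutes
    grid = np.zeros((7, n_ep), dtype=np.uint8)
    for day, intervals in enumerate(intervals_per_day):
        for start_min, end_min in intervals:
            grid[day, start_min // epoch_minutes : end_min // epoch_minutes] = 1
    return SleepEpochSeries(pid, grid, epoch_minutes)


@pytest.fixture
def clean_sleeper():
    """Asleep exactly 23:00-07:00 every day (epoch grid view)."""
    iv = [[(0, 7 * 60), (23 * 60, 24 * 60)]] * 7
    return series_from_intervals(iv)


def noise_free_config(**overrides):
    """Generator config with every stochastic sleep component switched off."""
    base = dict(
        n_participants=5,
        seed=0,
        chronotype_sd=0.0,
        duration_sd=0.0,
        duration_jitter_sd=0.0,
        onset_base_sd=0.0,
        offnight_prob_alpha=1e-6,
        offnight_prob_beta=1.0,
        fragility_prob_lo=0.0,
        fragility_prob_hi=0.0,
        awakening_rate=0.0,
        disrupt_awakening_rate=0.0,
        nap_prob_alpha=1e-6,
        nap_prob_beta=1.0,
        weekend_class_probs=(0.0, 0.0, 1.0),
        weekend_extra_sleep_hours=0.0,
        duration_mean=8.0,
        chronotype_mean=23.0,
        improve_alarm_nights=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A dense small cohort (boosted event rate) for model-level tests."""
    cfg = GeneratorConfig(n_participants=1500, seed=42, baseline_rate=0.02)
    return generate_cohort(cfg).frame()
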