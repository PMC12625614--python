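"""Sleep-behavior metrics from epoch-level sleep/wake series.

The central quantity is *routine sleep hours* (RSH): the number of fixed
clock-hour brackets (midnight-1 am, 1-2 am, ..., 11 pm-midnight) during which
a participant was asleep for at least 95% of the time, aggregated over the
seven nights of a one-week actigraphy study.  The 95% threshold admits on
average 3 minutes of wakefulness per bracket-hour, i.e. a budget of 21
minutes across the 7 days.  Companion metrics are the average sleep duration
(ASD, hours asleep per day), non-routine sleep hours (NRSH = ASD - RSH) and
average awake duration (AAD = 24 - ASD).

Brackets are clock-aligned and fixed in local time; no timezone or DST
handling is attempted.  The 95% rule is applied to the 7-day *aggregated*
asleep fraction per bracket (not per-day-then-every-day): only an aggregated
reading is compatible with an average wakefulness budget of 3 minutes per
bracket-hour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_DAYS = 7
N_BRACKETS = 24
MINUTES_PER_DAY = 1440
DEFAULT_THRESHOLD = 0.95
#: absolute guard when comparing asleep fractions against the threshold, so
#: that a fraction that is exactly the threshold up to float representation
#: (e.g. 0.95 stored as 0.9500000000000001) is never missed.
THRESHOLD_GUARD = 1e-12

WEEKDAYS = (1, 2, 3, 4, 5)
WEEKEND = (6, 7)

WEEKEND_BROKE = "broke"
WEEKEND_IMPROVED = "improved"
WEEKEND_MAINTAINED = "maintained"


class MetricsError(ValueError):
    """Invalid input to a sleep-metric computation."""


@dataclass
class SleepEpochSeries:
    """One participant's 7-day grid of binary asleep/awake epochs.

    Parameters
    ----------
    participant_id
        Identifier carried through to output tables.
    grid
        ``(7, E)`` array with entries in {0, 1}; 1 = asleep.  ``E`` is the
        number of epochs per day, ``1440 / epoch_minutes``.
    epoch_minutes
        Minutes per epoch; must divide 60.
    """

    participant_id: object
    grid: np.ndarray
    epoch_minutes: int = 5

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.shape[0] != N_DAYS:
            raise MetricsError(
                f"grid must have shape (7, E); got {g.shape}"
            )
        if 60 % self.epoch_minutes != 0:
            raise MetricsError(
                f"epoch_minutes must divide 60; got {self.epoch_minutes}"
            )
        expected = MINUTES_PER_DAY // self.epoch_minutes
        if g.shape[1] != expected:
            raise MetricsError(
                f"grid has {g.shape[1]} epochs/day; expected {expected} "
                f"for {self.epoch_minutes}-minute epochs"
            )
        if not np.isin(g, (0, 1)).all():
            raise MetricsError("grid entries must be 0 or 1")
        self.grid = g.astype(np.uint8, copy=False)

    @property
    def epochs_per_day(self) -> int:
        return self.grid.shape[1]

    @property
    def epochs_per_bracket(self) -> int:
        return 60 // self.epoch_minutes


@dataclass
class BracketFractions:
    """Asleep fractions per fixed clock-hour bracket.

    ``per_day`` is a ``(24, 7)`` matrix of per-day fractions; ``aggregated``
    is the unweighted mean of ``per_day`` over the selected ``days``.
    """

    per_day: np.ndarray
    aggregated: np.ndarray
    days: tuple


def bracket_fractions(
    series: SleepEpochSeries, days: Iterable[int] | None = None
) -> BracketFractions:
    """Fraction of time asleep within each of the 24 clock-hour brackets.

    ``days`` selects the day subset used for the aggregated fractions
    (1-based, default all 7); the per-day matrix always covers all days.
    """
    if days is None:
        days = tuple(range(1, N_DAYS + 1))
    else:
        days = tuple(days)
    if len(days) == 0:
        raise MetricsError("day subset must be non-empty")
    if not set(days) <= set(range(1, N_DAYS + 1)):
        raise MetricsError(f"days must be a subset of 1..7; got {days}")

    epb = series.epochs_per_bracket
    per_day = (
        series.grid.reshape(N_DAYS, N_BRACKETS, epb)
        .mean(axis=2, dtype=float)
        .T
    )
    idx = [d - 1 for d in days]
    aggregated = per_day[:, idx].mean(axis=1)
    return BracketFractions(per_day=per_day, aggregated=aggregated, days=days)


def routine_sleep_hours(
    fractions: BracketFractions | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> int:
    """Count brackets whose aggregated asleep fraction reaches ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise MetricsError(f"threshold must be in (0, 1); got {threshold}")
    agg = (
        fractions.aggregated
        if isinstance(fractions, BracketFractions)
        else np.asarray(fractions, dtype=float)
    )
    return int(np.count_nonzero(agg >= threshold - THRESHOLD_GUARD))


def average_sleep_duration(series: SleepEpochSeries) -> float:
    """Mean hours asleep per day over the 7-day grid."""
    return float(series.grid.sum()) * series.epoch_minutes / 60.0 / N_DAYS


def derived_metrics(asd: float, rsh: float) -> tuple[float, float]:
    """Non-routine sleep hours and average awake duration from (ASD, RSH).

    NRSH = ASD - RSH and AAD = 24 - ASD.  Raises if ASD < 0.95 * RSH, which
    cannot arise from the metric construction (every routine bracket
    contributes at least 0.95 h of average sleep).
    """
    if not (0 <= rsh <= 24 and 0 <= asd <= 24):
        raise MetricsError(f"asd and rsh must lie in [0, 24]; got ({asd}, {rsh})")
    if asd < DEFAULT_THRESHOLD * rsh - 1e-9:
        raise MetricsError(
            f"inconsistent metrics: asd={asd} < 0.95 * rsh={rsh}; routine "
            "brackets each contribute at least 0.95 h of average sleep"
        )
    return asd - rsh, 24.0 - asd


@dataclass
class SleepMetrics:
    """Per-participant sleep-behavior summary."""

    participant_id: object
    rsh: int
    asd: float
    nrsh: float
    aad: float
    rsh_weekday: int
    asd_weekday: float
    weekend_class: str


def weekend_decomposition(
    series: SleepEpochSeries, threshold: float = DEFAULT_THRESHOLD
) -> tuple[int, int, str]:
    """Weekday-only vs full-week routine sleep hours and the weekend class.

    Returns ``(rsh_weekday, rsh_allweek, weekend_class)`` where the class is
    ``"broke"`` if the full-week RSH falls below the weekday-only RSH
    (weekend behavior destroyed routine built during the week),
    ``"improved"`` if it exceeds it, and ``"maintained"`` on equality.
    """
    rsh_all = routine_sleep_hours(bracket_fractions(series), threshold)
    rsh_wd = routine_sleep_hours(bracket_fractions(series, WEEKDAYS), threshold)
    if rsh_all < rsh_wd:
        cls = WEEKEND_BROKE
    elif rsh_all > rsh_wd:
        cls = WEEKEND_IMPROVED
    else:
        cls = WEEKEND_MAINTAINED
    return rsh_wd, rsh_all, cls


def compute_metrics(
    series: SleepEpochSeries, threshold: float = DEFAULT_THRESHOLD
) -> SleepMetrics:
    """All sleep metrics for a single participant."""
    asd = average_sleep_duration(series)
    rsh = routine_sleep_hours(bracket_fractions(series), threshold)
    nrsh, aad = derived_metrics(asd, rsh)
    rsh_wd, _, cls = weekend_decomposition(series, threshold)
    wd_idx = [d - 1 for d in WEEKDAYS]
    asd_wd = (
        float(series.grid[wd_idx].sum())
        * series.epoch_minutes
        / 60.0
        / len(WEEKDAYS)
    )
    return SleepMetrics(
        participant_id=series.participant_id,
        rsh=rsh,
        asd=asd,
        nrsh=nrsh,
        aad=aad,
        rsh_weekday=rsh_wd,
        asd_weekday=asd_wd,
        weekend_class=cls,
    )


def cohort_metrics(
    series_iter: Iterable[SleepEpochSeries],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Metrics table (one row per participant) for a cohort of series."""
    rows = [compute_metrics(s, threshold) for s in series_iter]
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in rows],
            "rsh": [m.rsh for m in rows],
            "asd": [m.asd for m in rows],
            "nrsh": [m.nrsh for m in rows],
            "aad": [m.aad for m in rows],
            "rsh_weekday": [m.rsh_weekday for m in rows],
            "asd_weekday": [m.asd_weekday for m in rows],
            "weekend_class": [m.weekend_class for m in rows],
        }
    )


@dataclass
class ThresholdScan:
    """Population-mean RSH as a function of the bracket threshold."""

    thresholds: np.ndarray
    mean_rsh: np.ndarray
    selected: float
    drop_tolerance: float


def threshold_scan(
    series_list: Sequence[SleepEpochSeries] | np.ndarray,
    thresholds: np.ndarray | None = None,
) -> ThresholdScan:
    """Scan the routine threshold from 1% to 99% and pick the knee.

    For every threshold on the grid the population-mean RSH is computed.
    The curve is non-increasing in the threshold.  The selected threshold is
    the highest one *before* the curve starts to drop drastically towards
    zero: scanning upward from tau = 0.50, it is the first tau whose forward
    decrement ``meanRSH(tau) - meanRSH(tau + step)`` exceeds the drop
    tolerance (equivalently, the largest tau preceded only by in-tolerance
    decrements).  The tolerance is 5% of the curve's value at tau = 0.50, so
    smooth plateaus survive and cliff edges trigger.  The scan starts at
    0.50 because the drastic collapse necessarily lives in the upper tail;
    the low-threshold region carries structural day-count steps (a bracket
    slept through on exactly one or two of the seven days, e.g. by a napper)
    that say nothing about the routine threshold.  If no decrement exceeds
    the tolerance the last grid point is selected.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.995, 0.01), 2)
    thresholds = np.asarray(thresholds, dtype=float)

    if isinstance(series_list, np.ndarray) and series_list.ndim == 2:
        agg = series_list  # (n_participants, 24) aggregated fractions
    else:
        series_list = list(series_list)
        agg = np.array(
            [bracket_fractions(s).aggregated for s in series_list]
        )
    if agg.shape[0] < 2:
        raise MetricsError("threshold scan requires at least 2 participants")

    # mean RSH per threshold: count of brackets >= tau, averaged over cohort
    mean_rsh = (
        (agg[:, :, None] >= thresholds[None, None, :] - THRESHOLD_GUARD)
        .sum(axis=1)
        .mean(axis=0)
        .astype(float)
    )

    i50 = int(np.argmin(np.abs(thresholds - 0.50)))
    delta = 0.05 * mean_rsh[i50]
    decrements = mean_rsh[:-1] - mean_rsh[1:]
    offending = np.nonzero((decrements > delta) & (thresholds[:-1] >= 0.50))[0]
    if offending.size:
        selected = float(thresholds[offending[0]])
    else:
        selected = float(thresholds[-1])
    return ThresholdScan(
        thresholds=thresholds,
        mean_rsh=mean_rsh,
        selected=selected,
        drop_tolerance=float(delta),
    )
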