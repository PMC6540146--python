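"""Accelerometer epoch screening and objective outcome derivation.

Counts are recorded in 30-second epochs.  Screening follows the study
protocol: runs of at least 60 minutes of consecutive zero counts are
non-wear; wear bouts shorter than 60 minutes are also excluded; a day is
valid only with at least 10 hours of wear.  Two outcomes are derived over
valid days: mean counts per hour of wear, and the percentage of wear time
at or above a moderate-to-vigorous (MVPA) count cutpoint.  The cutpoint is
deliberately configuration-only: no defensible default exists for the
device/epoch combination, so callers must state one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EPOCHS_PER_HOUR = 120
EPOCHS_PER_DAY = 2880
NONWEAR_RUN_EPOCHS = 120  # >= 60 min of consecutive zeros
MIN_WEAR_BOUT_EPOCHS = 120  # wear bouts < 60 min are excluded
MIN_VALID_DAY_EPOCHS = 1200  # >= 10 h wear per day


@dataclass
class EpochSeries:
    """Per-day 30-s epoch count arrays for one participant."""

    participant_id: int
    days: list[str]
    counts: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.counts):
            raise ValueError("days and counts length mismatch")
        self.counts = [np.asarray(c, dtype=int) for c in self.counts]
        for c in self.counts:
            if (c < 0).any():
                raise ValueError("epoch counts must be non-negative")


@dataclass
class WearMask:
    """Boolean wear indicator per epoch, same shape as its EpochSeries."""

    days: list[str]
    wear: list[np.ndarray] = field(default_factory=list)

    def wear_hours(self, day_index: int) -> float:
        return float(self.wear[day_index].sum()) / EPOCHS_PER_HOUR


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_nonwear(series: EpochSeries) -> WearMask:
    """Flag non-wear epochs for every day of an epoch series.

    Pass 1 marks zero-count runs of at least 60 minutes (120 epochs) as
    non-wear; pass 2 then excludes wear bouts shorter than 60 consecutive
    minutes (short isolated bouts between non-wear runs).  Idempotent.
    """
    mask = WearMask(days=list(series.days))
    for counts in series.counts:
        wear = np.ones(counts.size, dtype=bool)
        for start, stop in _runs(counts == 0):
            if stop - start >= NONWEAR_RUN_EPOCHS:
                wear[start:stop] = False
        for start, stop in _runs(wear):
            if stop - start < MIN_WEAR_BOUT_EPOCHS:
                wear[start:stop] = False
        mask.wear.append(wear)
    return mask


def valid_days(mask: WearMask) -> list[str]:
    """Days with at least 10 hours (1200 epochs) of wear time."""
    return [
        day
        for i, day in enumerate(mask.days)
        if int(mask.wear[i].sum()) >= MIN_VALID_DAY_EPOCHS
    ]


def mean_counts_per_hour(
    series: EpochSeries, mask: WearMask, days: Sequence[str]
) -> float:
    """Total counts during wear on valid days divided by total wear hours.

    Raises when no valid day remains; callers treat that as participant
    exclusion (it feeds the cohort exclusion count).
    """
    wanted = set(days)
    total_counts = 0.0
    total_epochs = 0
    for i, day in enumerate(series.days):
        if day not in wanted:
            continue
        w = mask.wear[i]
        total_counts += float(series.counts[i][w].sum())
        total_epochs += int(w.sum())
    if total_epochs == 0:
        raise ValueError("no valid wear time: participant excluded")
    return total_counts / (total_epochs / EPOCHS_PER_HOUR)


def percent_time_mvpa(
    series: EpochSeries,
    mask: WearMask,
    days: Sequence[str],
    cutpoint: float | None = None,
) -> float:
    """Percent of wear epochs on valid days at or above the MVPA cutpoint."""
    if cutpoint is None or cutpoint <= 0:
        raise ValueError(
            "an explicit positive MVPA count cutpoint must be configured"
        )
    wanted = set(days)
    above = 0
    total = 0
    for i, day in enumerate(series.days):
        if day not in wanted:
            continue
        w = mask.wear[i]
        above += int((series.counts[i][w] >= cutpoint).sum())
        total += int(w.sum())
    if total == 0:
        raise ValueError("no valid wear time: participant excluded")
    return 100.0 * above / total


def screen_participant(
    series: EpochSeries, cutpoint: float, min_valid_days: int = 1
) -> dict | None:
    """Full screening for one participant; None when excluded.

    Returns the derived objective outcomes and wear summary for
    participants with at least ``min_valid_days`` valid days.
    """
    mask = detect_nonwear(series)
    days = valid_days(mask)
    if len(days) < min_valid_days:
        return None
    return {
        "participant_id": series.participant_id,
        "n_valid_days": len(days),
        "mean_counts_per_hour": mean_counts_per_hour(series, mask, days),
        "pct_mvpa": percent_time_mvpa(series, mask, days, cutpoint),
    }
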