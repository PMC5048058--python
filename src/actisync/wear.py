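"""Nonwear detection, joint exclusion, and valid-day screening.

A nonwear period is a run of at least ``zero_run_minutes`` (default 60)
consecutive zero minutes.  For the research device an optional Troiano-style
allowance admits up to ``research_spike_tolerance_minutes`` interior minutes
below ``research_spike_max_counts``; the strict zero-run rule (tolerance 0)
is the default.  The consumer stream exports no counts, so its "zero" signal
is configurable: by default a minute is consumer-zero iff steps == 0 AND
intensity code == 0, which avoids reading genuinely sedentary wear as
nonwear; a steps-only rule is available.

Minutes are flagged nonwear when they lie inside ANY qualifying window, so
the detector is equivalent to an exhaustive window scan (tests enforce this
against a brute-force oracle).  Runs may span midnight; day screening slices
by calendar date only after masking.  A day is valid when its joint-wear
minutes reach ``min_daily_joint_wear_minutes`` (default 480 = 8 waking
hours, boundary inclusive).
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device_io import DeviceMinuteSeries, RegisteredStream
from .errors import ConfigurationError

CONSUMER_ZERO_RULES = ("steps_and_intensity", "steps_only")


@dataclass(frozen=True)
class WearCriteria:
    zero_run_minutes: int = 60
    research_spike_tolerance_minutes: int = 0
    research_spike_max_counts: int = 100
    min_daily_joint_wear_minutes: int = 480
    consumer_zero_rule: str = "steps_and_intensity"

    def __post_init__(self) -> None:
        if self.zero_run_minutes < 1:
            raise ConfigurationError("zero_run_minutes must be >= 1")
        if not 0 <= self.research_spike_tolerance_minutes < self.zero_run_minutes:
            raise ConfigurationError("spike tolerance must lie in [0, zero_run_minutes)")
        if self.consumer_zero_rule not in CONSUMER_ZERO_RULES:
            raise ConfigurationError(f"consumer_zero_rule must be one of {CONSUMER_ZERO_RULES}")


def nonwear_runs(
    zero: np.ndarray,
    min_run: int,
    spike_tolerance: int = 0,
    spike_ok: np.ndarray | None = None,
) -> np.ndarray:
    """Mark minutes lying inside any qualifying zero run.

    A qualifying window starts and ends on a zero minute, has length
    >= ``min_run``, and contains at most ``spike_tolerance`` nonzero minutes,
    all of which must be allowed by ``spike_ok``.  Returns a boolean nonwear
    mask.  Implemented as a linear sweep over zero positions using the fact
    that the maximal admissible window end is nondecreasing in its start.
    """
    zero = np.asarray(zero, dtype=bool)
    n = len(zero)
    nonwear = np.zeros(n, dtype=bool)
    if n == 0:
        return nonwear
    nonzero = ~zero
    if spike_tolerance == 0:
        blocker = nonzero
    else:
        if spike_ok is None:
            spike_ok = np.zeros(n, dtype=bool)
        blocker = nonzero & ~np.asarray(spike_ok, dtype=bool)

    # next blocker at or after each position
    next_blocker = np.full(n + 1, n)
    for i in range(n - 1, -1, -1):
        next_blocker[i] = i if blocker[i] else next_blocker[i + 1]

    spike_pos = np.flatnonzero(nonzero & ~blocker)  # absorbable nonzero minutes
    zero_pos = np.flatnonzero(zero)

    # prev_zero[i]: last zero index <= i
    prev_zero = np.full(n, -1)
    last = -1
    for i in range(n):
        if zero[i]:
            last = i
        prev_zero[i] = last

    cur_end = -1
    for a in zero_pos:
        if spike_tolerance > 0:
            k = bisect_left(spike_pos, a)
            spike_limit = spike_pos[k + spike_tolerance] if k + spike_tolerance < len(spike_pos) else n
        else:
            spike_limit = n
        limit = min(next_blocker[a], spike_limit) - 1  # last admissible index
        e = prev_zero[limit] if limit >= 0 else -1
        if e >= a and e - a + 1 >= min_run:
            lo = max(a, cur_end + 1)
            if lo <= e:
                nonwear[lo : e + 1] = True
            cur_end = max(cur_end, e)
    return nonwear


def detect_nonwear_research(series: DeviceMinuteSeries, criteria: WearCriteria = WearCriteria()) -> pd.Series:
    """Wear mask for the research stream from its zero-count runs."""
    counts = series.data["counts"].to_numpy()
    zero = counts == 0
    spike_ok = (counts > 0) & (counts < criteria.research_spike_max_counts)
    mask = nonwear_runs(
        zero,
        criteria.zero_run_minutes,
        criteria.research_spike_tolerance_minutes,
        spike_ok,
    )
    return pd.Series(~mask, index=series.minutes, name="wear")


def detect_nonwear_consumer(series: DeviceMinuteSeries, criteria: WearCriteria = WearCriteria()) -> pd.Series:
    """Wear mask for the consumer stream from its zero-record runs."""
    steps = series.data["steps"].to_numpy()
    if criteria.consumer_zero_rule == "steps_only":
        zero = steps == 0
    else:
        zero = (steps == 0) & (series.data["intensity_code"].to_numpy() == 0)
    mask = nonwear_runs(zero, criteria.zero_run_minutes)
    return pd.Series(~mask, index=series.minutes, name="wear")


def apply_joint_exclusion(reg: RegisteredStream, criteria: WearCriteria = WearCriteria()) -> RegisteredStream:
    """Compute per-device wear masks and intersect them.

    Minutes flagged nonwear on either device are excluded from every
    downstream summary; ``joint_wear`` is the AND of the two masks.
    """
    research_wear = detect_nonwear_research(reg.research, criteria)
    consumer_wear = detect_nonwear_consumer(reg.consumer, criteria)
    research = reg.research.with_data(wear=research_wear)
    consumer = reg.consumer.with_data(wear=consumer_wear)
    return dataclasses.replace(
        reg,
        research=research,
        consumer=consumer,
        joint_wear=research_wear & consumer_wear,
    )


def screen_valid_days(reg: RegisteredStream, criteria: WearCriteria = WearCriteria()) -> set:
    """Calendar dates whose joint-wear minutes reach the daily minimum."""
    per_day = reg.joint_wear.groupby(reg.minutes.date).sum()
    return set(per_day.index[per_day >= criteria.min_daily_joint_wear_minutes])


def wear_report(reg: RegisteredStream, criteria: WearCriteria = WearCriteria()) -> pd.DataFrame:
    """Per-day wear tally: research/consumer/joint wear minutes and validity."""
    dates = reg.minutes.date
    out = pd.DataFrame(
        {
            "research_wear_min": reg.research.wear.groupby(dates).sum(),
            "consumer_wear_min": reg.consumer.wear.groupby(dates).sum(),
            "joint_wear_min": reg.joint_wear.groupby(dates).sum(),
        }
    )
    out["valid"] = (out["joint_wear_min"] >= criteria.min_daily_joint_wear_minutes).astype(int)
    out.index.name = "date"
    return out
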