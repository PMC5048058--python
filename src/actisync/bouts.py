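"""Exercise-journal parsing, bout validation against the research stream,
exercise-type categorisation, and per-bout minute-level summaries.

Participants journal up to 4 daily bouts of purposeful exercise (type label,
start and end clock time).  A reported bout is accepted when a window whose
boundaries each lie within ±5 minutes of the reported ones covers mostly
active minutes on the research stream.  Concretely: start and end offsets
are searched independently over [-tolerance, +tolerance]; a candidate window
must consist entirely of joint-wear minutes and its fraction of
non-sedentary minutes (research intensity code >= 1) must reach 0.8; among
qualifying candidates the one covering the most active minutes wins (a pure
fraction criterion would reward shrinking the window and clip true bout
minutes), ties broken by the higher active fraction, then the smallest total
boundary shift, then the earliest start.  Rejections are
reported with a reason, never silently dropped.

Exercise types are grouped into six categories by case-insensitive keyword
matching (walk, run or sports, bike, cardio dance, cardio machine, weights);
machine keywords are checked first so "running on a treadmill" lands in
cardio machine, and anything unmatched falls into ``other``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device_io import DeviceMinuteSeries, RegisteredStream
from .errors import DomainError, ParseError

CATEGORIES = ("walk", "run_or_sports", "bike", "cardio_dance", "cardio_machine", "weights", "other")

# Match order matters: machine-based wordings ("running on a treadmill",
# "stationary bike") must win over the bare run/bike keywords.
CATEGORY_KEYWORDS = (
    ("cardio_machine", ("treadmill", "elliptical", "stair-climber", "stair climber", "stairclimber", "stairmaster", "stationary bike", "rowing machine", "cardio machine")),
    ("cardio_dance", ("dance", "zumba", "aerobics")),
    ("run_or_sports", ("run", "jog", "sprint", "basketball", "football", "soccer", "frisbee", "tennis", "sports")),
    ("bike", ("bike", "biking", "cycling", "cycle")),
    ("weights", ("weight", "lifting", "strength", "resistance")),
    ("walk", ("walk", "hike", "hiking")),
)


@dataclass(frozen=True)
class JournalEntry:
    date: dt.date
    type_label: str
    start: dt.time
    end: dt.time

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParseError(f"journal entry on {self.date}: end {self.end} not after start {self.start}")


@dataclass(frozen=True)
class ValidatedBout:
    """A journal entry matched to the research stream."""

    participant: str
    category: str
    date: dt.date
    reported_start: pd.Timestamp
    reported_end: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    active_fraction: float

    @property
    def n_minutes(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(minutes=1))


@dataclass(frozen=True)
class BoutRejection:
    participant: str
    date: dt.date
    type_label: str
    reason: str


@dataclass(frozen=True)
class BoutSummary:
    """Per-device minute-level means over one validated bout."""

    bout: ValidatedBout
    research_steps: float
    research_mets: float
    research_intensity: float
    consumer_steps: float
    consumer_mets: float
    consumer_intensity: float


def categorize(type_label: str) -> str:
    """Exercise category for a free-text journal label."""
    if not type_label or not type_label.strip():
        raise DomainError("empty exercise label")
    label = type_label.lower()
    for category, keywords in CATEGORY_KEYWORDS:
        if any(k in label for k in keywords):
            return category
    return "other"


def read_journal(path) -> pd.DataFrame:
    """Read a journal CSV (``date,type,start,end``; HH:MM local times)."""
    raw = pd.read_csv(path, dtype={"type": str})
    for col in ("date", "type", "start", "end"):
        if col not in raw.columns:
            raise ParseError(f"{path}: journal missing column {col!r}")
    raw["date"] = pd.to_datetime(raw["date"]).dt.date
    return raw


def write_journal(journal: pd.DataFrame, path) -> None:
    journal.to_csv(path, index=False)


def journal_entries(journal: pd.DataFrame) -> list[JournalEntry]:
    entries = []
    for _, row in journal.iterrows():
        date = row["date"] if isinstance(row["date"], dt.date) else pd.to_datetime(row["date"]).date()
        start = dt.time(*map(int, str(row["start"]).split(":")[:2]))
        end = dt.time(*map(int, str(row["end"]).split(":")[:2]))
        entries.append(JournalEntry(date=date, type_label=str(row["type"]), start=start, end=end))
    per_day = pd.Series([e.date for e in entries]).value_counts()
    if (per_day > 4).any():
        bad = per_day.index[per_day > 4][0]
        raise ParseError(f"more than 4 journal entries on {bad}")
    return entries


def validate_bout(
    entry: JournalEntry,
    research: DeviceMinuteSeries,
    joint_wear: pd.Series | None = None,
    tolerance: int = 5,
    min_active_fraction: float = 0.8,
    participant: str = "",
) -> ValidatedBout | BoutRejection:
    """Match one journal entry to the scored research stream.

    Returns a :class:`ValidatedBout` whose boundaries are each within
    ``tolerance`` minutes of the reported ones, or a :class:`BoutRejection`
    with a reason.
    """
    codes = research.data["intensity_code"]
    if codes.isna().all():
        raise DomainError("research stream must be scored before bout validation")
    wear = joint_wear if joint_wear is not None else research.wear

    reported_start = pd.Timestamp(dt.datetime.combine(entry.date, entry.start))
    reported_end = pd.Timestamp(dt.datetime.combine(entry.date, entry.end))
    grid_start, grid_end = research.minutes[0], research.minutes[-1]
    if reported_end <= grid_start or reported_start > grid_end:
        return BoutRejection(participant, entry.date, entry.type_label, "no data")

    active = (codes >= 1).to_numpy()
    wear_arr = wear.to_numpy()
    index = research.minutes

    best = None  # (fraction, total_shift, start) to maximise / minimise / minimise
    one_min = pd.Timedelta(minutes=1)
    for ds in range(-tolerance, tolerance + 1):
        for de in range(-tolerance, tolerance + 1):
            start = reported_start + ds * one_min
            end = reported_end + de * one_min
            if end <= start or start < grid_start or end > grid_end + one_min:
                continue
            i0 = index.searchsorted(start)
            i1 = index.searchsorted(end)  # exclusive
            if i1 <= i0:
                continue
            if not wear_arr[i0:i1].all():
                continue
            n_active = int(active[i0:i1].sum())
            frac = n_active / (i1 - i0)
            if frac < min_active_fraction:
                continue
            key = (-n_active, -frac, abs(ds) + abs(de), start)
            if best is None or key < best[0]:
                best = (key, start, end, frac)
    if best is None:
        return BoutRejection(
            participant, entry.date, entry.type_label,
            "no candidate window met the activity/wear criteria",
        )
    _, start, end, frac = best
    return ValidatedBout(
        participant=participant,
        category=categorize(entry.type_label),
        date=entry.date,
        reported_start=reported_start,
        reported_end=reported_end,
        start=start,
        end=end,
        active_fraction=frac,
    )


def merge_overlapping(bouts: list[ValidatedBout]) -> list[ValidatedBout]:
    """Merge validated bouts sharing >= 1 minute within a participant-day.

    Prevents double-counting minutes in pooled bout summaries; the merged
    bout keeps the category of its longest constituent.
    """
    out: list[ValidatedBout] = []
    by_key: dict = {}
    for b in bouts:
        by_key.setdefault((b.participant, b.date), []).append(b)
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda b: (b.start, b.end))
        current = group[0]
        longest = group[0]
        for b in group[1:]:
            if b.start < current.end:  # shares at least one minute
                if b.n_minutes > longest.n_minutes:
                    longest = b
                current = ValidatedBout(
                    participant=current.participant,
                    category=longest.category,
                    date=current.date,
                    reported_start=current.reported_start,
                    reported_end=max(current.reported_end, b.reported_end),
                    start=current.start,
                    end=max(current.end, b.end),
                    active_fraction=current.active_fraction,
                )
            else:
                out.append(current)
                current = b
                longest = b
        out.append(current)
    return out


def summarize_bout(reg: RegisteredStream, bout: ValidatedBout) -> BoutSummary:
    """Minute-level means of steps, METs, and intensity score per device.

    Research intensity uses the cut-point codes written by scoring; consumer
    intensity uses the device's exported codes.
    """
    end_label = bout.end - pd.Timedelta(minutes=1)
    res = reg.research.data.loc[bout.start : end_label]
    con = reg.consumer.data.loc[bout.start : end_label]
    if len(res) == 0:
        raise DomainError("zero-length bout")
    return BoutSummary(
        bout=bout,
        research_steps=float(res["steps"].mean()),
        research_mets=float(res["mets"].mean()),
        research_intensity=float(res["intensity_code"].mean()),
        consumer_steps=float(con["steps"].mean()),
        consumer_mets=float(con["mets"].mean()),
        consumer_intensity=float(con["intensity_code"].mean()),
    )


def bout_table(
    accepted: list[BoutSummary], rejected: list[BoutRejection]
) -> pd.DataFrame:
    """Flat per-bout export: validated spans, summaries, rejection reasons."""
    rows = []
    for s in accepted:
        b = s.bout
        rows.append(
            {
                "participant": b.participant,
                "category": b.category,
                "reported_start": b.reported_start,
                "reported_end": b.reported_end,
                "validated_start": b.start,
                "validated_end": b.end,
                "n_minutes": b.n_minutes,
                "research_steps": s.research_steps,
                "research_mets": s.research_mets,
                "research_intensity": s.research_intensity,
                "consumer_steps": s.consumer_steps,
                "consumer_mets": s.consumer_mets,
                "consumer_intensity": s.consumer_intensity,
                "rejection_reason": "",
            }
        )
    for r in rejected:
        rows.append(
            {
                "participant": r.participant,
                "category": categorize(r.type_label),
                "rejection_reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
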