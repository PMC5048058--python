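"""Device export I/O, epoch aggregation, and two-stream time registration.

Both monitors are reduced to a single in-memory container, a
:class:`DeviceMinuteSeries`: a gapless 60-second grid carrying counts
(research device only), steps, METs, an intensity code in {0,1,2,3}, and a
wear mask.  ``register`` intersects two such grids into a
:class:`RegisteredStream`, the unit every downstream stage consumes.

CSV dialects (the I/O contract):

* research export:  ``timestamp,axis1,axis2,axis3,vm,steps`` — ``vm`` is the
  per-epoch vector-magnitude count; when absent it is computed as the rounded
  Euclidean norm of the three axes.
* consumer export:  ``timestamp,steps,mets,intensity`` — ``mets`` is exported
  as an integer at ``met_scale`` times MET units (Fitabase-style minute files
  use 10), ``intensity`` is the device's own 0–3 code.

A record labelled 10:07 covers the half-open minute [10:07:00, 10:08:00).
Timestamps are local clock time; no time-zone arithmetic is performed, since
the two devices are worn concurrently and synchronised at setup.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, RegistrationError

RESEARCH = "research"
CONSUMER = "consumer"

#: epoch lengths (seconds) accepted by the research-export reader
VALID_EPOCH_SECONDS = (1, 5, 10, 15, 30, 60)

SERIES_COLUMNS = ("counts", "steps", "mets", "intensity_code", "wear")


@dataclass
class LoadReport:
    """Provenance of a single export load: what was filled or dropped."""

    path: str = ""
    n_rows: int = 0
    filled_minutes: list = field(default_factory=list)
    dropped_partial_minutes: list = field(default_factory=list)

    @property
    def n_filled(self) -> int:
        return len(self.filled_minutes)


@dataclass
class DeviceMinuteSeries:
    """One device's uniform 1-minute grid.

    ``data`` is indexed by minute start (DatetimeIndex, strictly increasing,
    constant 60-s spacing, no duplicates) with columns ``counts`` (float,
    NaN on the consumer stream which exports no counts), ``steps`` (int),
    ``mets`` (float, NaN until scored on the research stream),
    ``intensity_code`` (float in {0,1,2,3} or NaN) and ``wear`` (bool).
    """

    device: str
    data: pd.DataFrame
    report: LoadReport | None = dataclasses.field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.device not in (RESEARCH, CONSUMER):
            raise ConfigurationError(f"unknown device kind {self.device!r}")
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ParseError("series index must be a DatetimeIndex")
        if len(df) == 0:
            raise ParseError("empty device series")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicated timestamp at {dup}")
        deltas = np.diff(df.index.asi8)
        if len(deltas) and not np.all(deltas == 60_000_000_000):
            raise ParseError("minute grid must be strictly increasing with 60-s spacing")
        for col in SERIES_COLUMNS:
            if col not in df.columns:
                raise ParseError(f"series missing column {col!r}")
        counts = df["counts"]
        if (counts.dropna() < 0).any():
            raise ParseError("negative counts")
        if (df["steps"] < 0).any():
            raise ParseError("negative steps")
        code = df["intensity_code"].dropna()
        if len(code) and not code.isin([0, 1, 2, 3]).all():
            bad = code[~code.isin([0, 1, 2, 3])].iloc[0]
            raise ParseError(f"intensity code {bad} outside 0-3")

    # -- convenience accessors -------------------------------------------------
    @property
    def minutes(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def wear(self) -> pd.Series:
        return self.data["wear"]

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, **columns) -> "DeviceMinuteSeries":
        """Return a copy with the given columns replaced."""
        df = self.data.copy()
        for name, values in columns.items():
            df[name] = values
        return dataclasses.replace(self, data=df)

    def slice(self, start, end) -> "DeviceMinuteSeries":
        """Inclusive slice on minute labels."""
        return dataclasses.replace(self, data=self.data.loc[start:end])


@dataclass
class RegisteredStream:
    """Two time-aligned device series on an identical minute grid.

    ``joint_wear`` is the minute-wise AND of the two wear masks; it is the
    only mask downstream summaries consume.  ``valid_days`` is filled by the
    wear-screening stage.
    """

    research: DeviceMinuteSeries
    consumer: DeviceMinuteSeries
    joint_wear: pd.Series = None
    valid_days: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.research.minutes.equals(self.consumer.minutes):
            raise RegistrationError("registered series must share one minute grid")
        if self.joint_wear is None:
            self.joint_wear = self.research.wear & self.consumer.wear

    @property
    def minutes(self) -> pd.DatetimeIndex:
        return self.research.minutes


def _finalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in SERIES_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["steps"] = df["steps"].astype(np.int64)
    df["counts"] = df["counts"].astype(float)
    df["mets"] = df["mets"].astype(float)
    df["intensity_code"] = df["intensity_code"].astype(float)
    df["wear"] = df["wear"].fillna(True).astype(bool) if df["wear"].isna().any() else df["wear"].astype(bool)
    return df[list(SERIES_COLUMNS)]


def _read_sorted(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    if "timestamp" not in raw.columns:
        raise ParseError(f"{path}: missing 'timestamp' column")
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    raw = raw.sort_values("timestamp", kind="stable").set_index("timestamp")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated timestamp at {dup}")
    return raw


def aggregate_to_minutes(frame: pd.DataFrame, epoch_seconds: int) -> tuple[pd.DataFrame, list]:
    """Sum sub-minute epochs of ``counts`` and ``steps`` into clock minutes.

    ``frame`` is indexed by epoch start at ``epoch_seconds`` resolution and
    must be gapless within each minute.  Minutes with fewer than
    ``60 // epoch_seconds`` epochs (partial leading/trailing minutes) are
    dropped and returned in the second element.
    """
    if 60 % epoch_seconds != 0:
        raise ConfigurationError(f"epoch of {epoch_seconds}s does not divide 60s")
    per_minute = 60 // epoch_seconds
    if epoch_seconds == 60:
        return frame, []
    minute = frame.index.floor("min")
    grouped = frame.groupby(minute)
    sizes = grouped.size()
    complete = sizes[sizes == per_minute].index
    dropped = list(sizes.index.difference(complete))
    agg = grouped.sum(numeric_only=True).loc[complete]
    return agg, dropped


def read_research_export(path, epoch_seconds: int = 60) -> DeviceMinuteSeries:
    """Read an ActiGraph-style count export into a gapless minute series.

    Finer epochs are summed to 60 s.  Missing minutes inside the observation
    span are inserted with zero counts/steps and listed in the attached
    :class:`LoadReport` so the nonwear rule can see them.
    """
    if epoch_seconds not in VALID_EPOCH_SECONDS:
        raise ConfigurationError(f"epoch_seconds must be one of {VALID_EPOCH_SECONDS}")
    raw = _read_sorted(path)
    report = LoadReport(path=str(path), n_rows=len(raw))

    if "vm" in raw.columns and raw["vm"].notna().all():
        vm = raw["vm"].astype(float)
    else:
        axes = [raw[c].astype(float) for c in ("axis1", "axis2", "axis3")]
        vm = np.sqrt(axes[0] ** 2 + axes[1] ** 2 + axes[2] ** 2).round()
    if (vm < 0).any():
        raise ParseError(f"{path}: negative counts at {vm.index[vm < 0][0]}")
    frame = pd.DataFrame({"counts": vm, "steps": raw["steps"].astype(float)}, index=raw.index)

    frame, dropped = aggregate_to_minutes(frame, epoch_seconds)
    report.dropped_partial_minutes = dropped

    full = pd.date_range(frame.index[0], frame.index[-1], freq="min")
    missing = full.difference(frame.index)
    frame = frame.reindex(full, fill_value=0.0)
    report.filled_minutes = list(missing)

    df = _finalize_frame(
        pd.DataFrame(
            {"counts": frame["counts"], "steps": frame["steps"], "wear": True},
            index=frame.index,
        )
    )
    return DeviceMinuteSeries(device=RESEARCH, data=df, report=report)


def read_consumer_export(path, met_scale: float = 10.0) -> DeviceMinuteSeries:
    """Read a Fitabase-style minute export.

    Exported MET integers are divided by ``met_scale`` (default 10, the
    dominant dialect: a stored 10 means 1.0 MET, resting).  Gaps inside the
    span are filled with steps=0, intensity=0, METs=1.0 so that the
    consumer zero-run nonwear rule can capture them.
    """
    if met_scale <= 0:
        raise ConfigurationError("met_scale must be positive")
    raw = _read_sorted(path)
    report = LoadReport(path=str(path), n_rows=len(raw))

    intensity = raw["intensity"].astype(float)
    if not intensity.isin([0, 1, 2, 3]).all():
        bad = raw.index[~intensity.isin([0, 1, 2, 3])][0]
        raise ParseError(f"{path}: intensity code outside 0-3 at {bad}")
    frame = pd.DataFrame(
        {
            "steps": raw["steps"].astype(float),
            "mets": raw["mets"].astype(float) / met_scale,
            "intensity_code": intensity,
        },
        index=raw.index,
    )
    full = pd.date_range(frame.index[0], frame.index[-1], freq="min")
    missing = full.difference(frame.index)
    frame = frame.reindex(full)
    frame["steps"] = frame["steps"].fillna(0.0)
    frame["mets"] = frame["mets"].fillna(1.0)
    frame["intensity_code"] = frame["intensity_code"].fillna(0.0)
    report.filled_minutes = list(missing)

    frame["wear"] = True
    return DeviceMinuteSeries(device=CONSUMER, data=_finalize_frame(frame), report=report)


def write_research_export(series: DeviceMinuteSeries, path) -> None:
    """Write the research dialect; counts are stored on ``axis1`` with the
    ``vm`` column equal to the vector magnitude (round-trip exact)."""
    df = series.data
    out = pd.DataFrame(
        {
            "timestamp": df.index,
            "axis1": df["counts"].astype(np.int64),
            "axis2": 0,
            "axis3": 0,
            "vm": df["counts"].astype(np.int64),
            "steps": df["steps"].astype(np.int64),
        }
    )
    out.to_csv(path, index=False)


def write_consumer_export(series: DeviceMinuteSeries, path, met_scale: float = 10.0) -> None:
    df = series.data
    out = pd.DataFrame(
        {
            "timestamp": df.index,
            "steps": df["steps"].astype(np.int64),
            "mets": (df["mets"] * met_scale).round().astype(np.int64),
            "intensity": df["intensity_code"].astype(np.int64),
        }
    )
    out.to_csv(path, index=False)


def register(research: DeviceMinuteSeries, consumer: DeviceMinuteSeries) -> RegisteredStream:
    """Time-register two 60-s series onto the intersection of their spans.

    Minutes present in one stream only are excluded; per-device totals over
    the common grid are untouched.  Registration is symmetric in coverage:
    swapping arguments changes labels only, never the grid.
    """
    start = max(research.minutes[0], consumer.minutes[0])
    end = min(research.minutes[-1], consumer.minutes[-1])
    if start > end:
        raise RegistrationError(
            f"no overlap: research ends {research.minutes[-1]}, consumer ends {consumer.minutes[-1]}"
        )
    return RegisteredStream(research=research.slice(start, end), consumer=consumer.slice(start, end))
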