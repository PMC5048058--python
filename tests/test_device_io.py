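"""Device export I/O: dialect parsing, epoch aggregation, registration."""

import numpy as np
import pandas as pd
import pytest

from actisync import (
    ParseError,
    RegistrationError,
    aggregate_to_minutes,
    read_consumer_export,
    read_research_export,
    register,
    write_consumer_export,
    write_research_export,
)
from actisync.device_io import CONSUMER, RESEARCH
from actisync.errors import ConfigurationError

from conftest import make_series


def _write_research_csv(path, timestamps, counts, steps=None, with_vm=True):
    steps = steps if steps is not None else [0] * len(counts)
    df = pd.DataFrame({"timestamp": timestamps, "axis1": counts, "axis2": 0, "axis3": 0, "steps": steps})
    if with_vm:
        df["vm"] = counts
    path_cols = ["timestamp", "axis1", "axis2", "axis3"] + (["vm"] if with_vm else []) + ["steps"]
    df[path_cols].to_csv(path, index=False)


class TestReadResearch:
    def test_hour_of_zero_epochs(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=60, freq="min")
        f = tmp_path / "r.csv"
        _write_research_csv(f, ts, [0] * 60)
        series = read_research_export(f)
        assert len(series) == 60
        assert (series.data["counts"] == 0).all()

    def test_duplicate_timestamp_names_minute(self, tmp_path):
        ts = list(pd.date_range("2024-03-01 09:00", periods=3, freq="min"))
        ts.append(ts[1])
        f = tmp_path / "r.csv"
        _write_research_csv(f, ts, [1, 2, 3, 4])
        with pytest.raises(ParseError, match="09:01"):
            read_research_export(f)

    def test_ten_second_epochs_sum_to_minute(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=6, freq="10s")
        f = tmp_path / "r.csv"
        _write_research_csv(f, ts, [10, 20, 30, 40, 50, 60])
        series = read_research_export(f, epoch_seconds=10)
        assert len(series) == 1
        assert series.data["counts"].iloc[0] == 210

    def test_vm_computed_from_axes_when_absent(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=1, freq="min")
        f = tmp_path / "r.csv"
        pd.DataFrame(
            {"timestamp": ts, "axis1": [3], "axis2": [4], "axis3": [0], "steps": [0]}
        ).to_csv(f, index=False)
        series = read_research_export(f)
        assert series.data["counts"].iloc[0] == 5  # rounded Euclidean norm

    def test_interior_gap_zero_filled_and_reported(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=10, freq="min").delete([4, 5])
        f = tmp_path / "r.csv"
        _write_research_csv(f, ts, [100] * 8)
        series = read_research_export(f)
        assert len(series) == 10
        assert series.data["counts"].iloc[4] == 0
        assert series.report.n_filled == 2

    def test_negative_counts_rejected(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=2, freq="min")
        f = tmp_path / "r.csv"
        _write_research_csv(f, ts, [5, -1])
        with pytest.raises(ParseError, match="negative"):
            read_research_export(f)


class TestAggregate:
    def test_sixty_second_identity(self):
        idx = pd.date_range("2024-03-01 09:00", periods=5, freq="min")
        frame = pd.DataFrame({"counts": range(5), "steps": range(5)}, index=idx)
        agg, dropped = aggregate_to_minutes(frame, 60)
        pd.testing.assert_frame_equal(agg, frame)
        assert dropped == []

    @pytest.mark.parametrize(
        "epoch,counts,steps,exp_counts,exp_steps",
        [
            (30, [5, 7], [0, 0], 12, 0),
            (15, [1, 1, 1, 1], [2, 2, 2, 2], 4, 8),
        ],
    )
    def test_hand_sums(self, epoch, counts, steps, exp_counts, exp_steps):
        idx = pd.date_range("2024-03-01 09:00", periods=len(counts), freq=f"{epoch}s")
        frame = pd.DataFrame({"counts": counts, "steps": steps}, index=idx)
        agg, dropped = aggregate_to_minutes(frame, epoch)
        assert agg["counts"].iloc[0] == exp_counts
        assert agg["steps"].iloc[0] == exp_steps
        assert dropped == []

    def test_partial_trailing_minute_dropped(self):
        idx = pd.date_range("2024-03-01 09:00", periods=9, freq="15s")  # 2nd minute partial
        frame = pd.DataFrame({"counts": [1] * 9, "steps": [0] * 9}, index=idx)
        agg, dropped = aggregate_to_minutes(frame, 15)
        assert len(agg) == 2
        assert len(dropped) == 1

    def test_epoch_not_dividing_minute(self):
        idx = pd.date_range("2024-03-01 09:00", periods=2, freq="25s")
        frame = pd.DataFrame({"counts": [1, 1], "steps": [0, 0]}, index=idx)
        with pytest.raises(ConfigurationError):
            aggregate_to_minutes(frame, 25)

    def test_aggregation_conserves_totals(self):
        rng = np.random.default_rng(5)
        idx = pd.date_range("2024-03-01 09:00", periods=240, freq="15s")  # whole minutes
        frame = pd.DataFrame(
            {"counts": rng.integers(0, 500, 240), "steps": rng.integers(0, 4, 240)}, index=idx
        )
        agg, dropped = aggregate_to_minutes(frame, 15)
        assert dropped == []
        assert agg["counts"].sum() == frame["counts"].sum()
        assert agg["steps"].sum() == frame["steps"].sum()


class TestReadConsumer:
    @pytest.mark.parametrize("raw,scale,expected", [(10, 10, 1.0), (32, 10, 3.2), (2.0, 1, 2.0)])
    def test_met_scaling(self, tmp_path, raw, scale, expected):
        f = tmp_path / "c.csv"
        pd.DataFrame(
            {"timestamp": ["2024-03-01 09:00"], "steps": [0], "mets": [raw], "intensity": [0]}
        ).to_csv(f, index=False)
        series = read_consumer_export(f, met_scale=scale)
        assert series.data["mets"].iloc[0] == pytest.approx(expected)

    def test_bad_intensity_code(self, tmp_path):
        f = tmp_path / "c.csv"
        pd.DataFrame(
            {"timestamp": ["2024-03-01 09:00"], "steps": [0], "mets": [10], "intensity": [5]}
        ).to_csv(f, index=False)
        with pytest.raises(ParseError, match="intensity"):
            read_consumer_export(f)

    def test_gap_filled_as_resting(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=5, freq="min").delete(2)
        f = tmp_path / "c.csv"
        pd.DataFrame(
            {"timestamp": ts, "steps": [9] * 4, "mets": [25] * 4, "intensity": [1] * 4}
        ).to_csv(f, index=False)
        series = read_consumer_export(f)
        filled = series.data.iloc[2]
        assert filled["steps"] == 0 and filled["intensity_code"] == 0 and filled["mets"] == 1.0


class TestRoundTrip:
    def test_research_round_trip(self, tmp_path, identity_cohort):
        participants, _ = identity_cohort
        series = participants[0].research
        f = tmp_path / "r.csv"
        write_research_export(series, f)
        back = read_research_export(f)
        pd.testing.assert_series_equal(back.data["counts"], series.data["counts"])
        pd.testing.assert_series_equal(back.data["steps"], series.data["steps"])

    def test_consumer_round_trip_to_dialect_precision(self, tmp_path, identity_cohort):
        participants, _ = identity_cohort
        series = participants[0].consumer
        f = tmp_path / "c.csv"
        write_consumer_export(series, f, met_scale=10)
        back = read_consumer_export(f, met_scale=10)
        pd.testing.assert_series_equal(back.data["steps"], series.data["steps"])
        pd.testing.assert_series_equal(back.data["intensity_code"], series.data["intensity_code"])
        # METs survive to the dialect's 0.1-MET precision
        assert (back.data["mets"] - series.data["mets"]).abs().max() <= 0.05 + 1e-12


class TestRegister:
    def test_identical_grids(self):
        r = make_series(RESEARCH, counts=[1] * 30)
        c = make_series(CONSUMER, steps=[1] * 30, mets=[1.0] * 30, intensity=[0] * 30)
        reg = register(r, c)
        assert len(reg.minutes) == 30

    def test_interval_intersection(self):
        r = make_series(RESEARCH, counts=[1] * 100, start="2024-01-01 00:00")
        c = make_series(CONSUMER, steps=[0] * 100, intensity=[0] * 100, start="2024-01-01 00:50")
        reg = register(r, c)
        assert reg.minutes[0] == pd.Timestamp("2024-01-01 00:50")
        assert reg.minutes[-1] == pd.Timestamp("2024-01-01 01:39")
        assert len(reg.minutes) == 50

    def test_registration_preserves_totals_on_common_grid(self):
        rng = np.random.default_rng(0)
        r = make_series(RESEARCH, counts=rng.integers(0, 100, 80), start="2024-01-01 00:00")
        c = make_series(CONSUMER, steps=rng.integers(0, 10, 80), intensity=[0] * 80, start="2024-01-01 00:20")
        reg = register(r, c)
        lo, hi = reg.minutes[0], reg.minutes[-1]
        assert reg.research.data["counts"].sum() == r.data.loc[lo:hi, "counts"].sum()
        assert reg.consumer.data["steps"].sum() == c.data.loc[lo:hi, "steps"].sum()

    def test_empty_intersection(self):
        r = make_series(RESEARCH, counts=[1] * 10, start="2024-01-01 00:00")
        c = make_series(CONSUMER, steps=[0] * 10, intensity=[0] * 10, start="2024-01-02 00:00")
        with pytest.raises(RegistrationError):
            register(r, c)

    def test_shuffled_rows_equal_sorted(self, tmp_path):
        ts = pd.date_range("2024-03-01 09:00", periods=50, freq="min")
        counts = np.arange(50)
        f_sorted, f_shuffled = tmp_path / "s.csv", tmp_path / "p.csv"
        _write_research_csv(f_sorted, ts, counts)
        perm = np.random.default_rng(3).permutation(50)
        _write_research_csv(f_shuffled, ts[perm], counts[perm])
        a = read_research_export(f_sorted)
        b = read_research_export(f_shuffled)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_swap_symmetry_of_grid(self):
        r = make_series(RESEARCH, counts=[1] * 100, start="2024-01-01 00:00")
        c = make_series(CONSUMER, steps=[0] * 100, intensity=[0] * 100, start="2024-01-01 00:50")
        grid_rc = register(r, c).minutes
        # device roles are fixed by the series, so swap coverage instead
        r2 = make_series(RESEARCH, counts=[1] * 100, start="2024-01-01 00:50")
        c2 = make_series(CONSUMER, steps=[0] * 100, intensity=[0] * 100, start="2024-01-01 00:00")
        grid_cr = register(r2, c2).minutes
        assert grid_rc.equals(grid_cr)
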