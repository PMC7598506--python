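"""Epoch processing: ingestion, non-wear, sleep masking, day summaries,
validity filtering."""

import numpy as np
import pandas as pd
import pytest

from sedtemp import accelerometry as acc
from conftest import make_stream


def naive_zero_runs(sig, min_len):
    """Brute-force O(n) run scanner used as the independent oracle."""
    runs, start = [], None
    for i, v in enumerate(sig):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(sig) - start >= min_len:
        runs.append((start, len(sig)))
    return runs


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

class TestReadEpochCsv:
    def _write(self, tmp_path, rows):
        p = tmp_path / "epochs.csv"
        p.write_text("child_id,timestamp,x,y,z\n" + "\n".join(rows) + "\n")
        return p

    def test_roundtrip_and_sort(self, tmp_path):
        rows = [
            f"c1,2014-03-10T08:00:{s:02d},10,1,2" for s in (20, 0, 50, 10, 40, 30)
        ]
        streams = acc.read_epoch_csv(self._write(tmp_path, rows))
        st = streams["c1"]
        assert len(st) == 6
        assert st.timestamps.is_monotonic_increasing

    def test_shuffled_equals_sorted(self, tmp_path):
        rows = [f"c1,2014-03-10T08:00:{s:02d},{s},0,0" for s in (0, 10, 20, 30)]
        a = acc.read_epoch_csv(self._write(tmp_path, rows))["c1"]
        b = acc.read_epoch_csv(self._write(tmp_path, rows[::-1]))["c1"]
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_negative_count_rejected(self, tmp_path):
        p = self._write(tmp_path, ["c1,2014-03-10T08:00:00,-4,0,0"])
        with pytest.raises(acc.EpochStreamError, match="negative"):
            acc.read_epoch_csv(p)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        rows = ["c1,2014-03-10T08:00:00,1,0,0", "c1,2014-03-10T08:00:00,2,0,0"]
        with pytest.raises(acc.EpochStreamError, match="duplicate"):
            acc.read_epoch_csv(self._write(tmp_path, rows))


@pytest.mark.parametrize(
    "xyz, expected",
    [((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((1, 2, 2), 3.0)],
)
def test_vector_magnitude(xyz, expected):
    assert acc.vector_magnitude(*xyz) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# non-wear detection
# ---------------------------------------------------------------------------

class TestDetectNonwear:
    def test_run_equal_to_threshold_flagged(self):
        # 120 zero epochs = exactly 20 minutes, flanked by activity
        x = np.r_[np.full(5, 100), np.zeros(120, int), np.full(5, 100)]
        runs = acc.detect_nonwear(make_stream(x), "x_axis", 20)
        assert runs == [(5, 125)]

    def test_run_below_threshold_ignored(self):
        x = np.r_[np.full(5, 100), np.zeros(119, int), np.full(5, 100)]
        assert acc.detect_nonwear(make_stream(x), "x_axis", 20) == []

    def test_all_zero_stream_single_interval(self):
        x = np.zeros(720, int)  # 2 h
        assert acc.detect_nonwear(make_stream(x), "x_axis", 20) == [(0, 720)]

    def test_truncated_runs_at_edges_qualify(self):
        x = np.r_[np.zeros(130, int), np.full(10, 50), np.zeros(125, int)]
        runs = acc.detect_nonwear(make_stream(x), "x_axis", 20)
        assert runs == [(0, 130), (140, 265)]

    def test_vm_signal_uses_all_axes(self):
        # x zero throughout, but y active in the middle breaks the VM run
        x = np.zeros(300, int)
        y = np.r_[np.zeros(140, int), np.full(20, 9), np.zeros(140, int)]
        vm_runs = acc.detect_nonwear(make_stream(x, y=y), "vector_magnitude", 20)
        x_runs = acc.detect_nonwear(make_stream(x, y=y), "x_axis", 20)
        assert vm_runs == [(0, 140), (160, 300)]
        assert x_runs == [(0, 300)]

    @pytest.mark.parametrize("signal", ["x_axis", "vector_magnitude"])
    @pytest.mark.parametrize("min_run", [20, 30])
    def test_oracle_equivalence_random_streams(self, rng, signal, min_run):
        """Vectorised detector agrees with the brute-force scanner on 250
        random streams per variant (1,000 total)."""
        for _ in range(250):
            n = int(rng.integers(50, 800))
            # sparse nonzero values to produce plenty of long zero runs
            x = rng.integers(0, 3, n) * rng.integers(0, 400, n)
            y = rng.integers(0, 2, n) * rng.integers(0, 50, n)
            st = make_stream(x, y=y)
            sig = (
                st.counts("x")
                if signal == "x_axis"
                else acc.vector_magnitude(st.counts("x"), st.counts("y"), st.counts("z"))
            )
            expected = naive_zero_runs(sig, min_run * 6)
            assert acc.detect_nonwear(st, signal, min_run) == expected

    def test_monotone_in_threshold(self, rng):
        """Raising 20 -> 30 min never increases total flagged time."""
        for _ in range(60):
            n = int(rng.integers(200, 2000))
            x = rng.integers(0, 2, n) * rng.integers(0, 400, n)
            st = make_stream(x)
            t20 = sum(b - a for a, b in acc.detect_nonwear(st, "x_axis", 20))
            t30 = sum(b - a for a, b in acc.detect_nonwear(st, "x_axis", 30))
            assert t30 <= t20

    def test_bad_config_rejected(self):
        st = make_stream(np.zeros(10, int))
        with pytest.raises(ValueError):
            acc.detect_nonwear(st, "magnitude", 20)
        with pytest.raises(ValueError):
            acc.detect_nonwear(st, "x_axis", 25)


# ---------------------------------------------------------------------------
# wear mask
# ---------------------------------------------------------------------------

class TestApplySleep:
    def test_no_intervals_all_awake(self):
        st = make_stream(np.full(60, 10))
        mask = acc.apply_sleep(st, None, None)
        assert (mask == acc.WORN_AWAKE).all()

    def test_sleep_interval_masks_epochs(self):
        st = make_stream(np.full(8640, 10), start="2014-03-10 00:00:00")
        sleep = pd.DataFrame(
            {"child_id": ["c0001"], "start": ["2014-03-10 00:00:00"],
             "end": ["2014-03-10 07:50:00"], "kind": ["night"]}
        )
        mask = acc.apply_sleep(st, sleep, None)
        n_sleep = 7 * 360 + 50 * 6
        assert (mask[:n_sleep] == acc.WORN_ASLEEP).all()
        assert (mask[n_sleep:] == acc.WORN_AWAKE).all()

    def test_nonwear_precedence_over_sleep(self):
        st = make_stream(np.zeros(8640, int))
        sleep = pd.DataFrame(
            {"child_id": ["c0001"], "start": ["2014-03-10 01:00:00"],
             "end": ["2014-03-10 05:00:00"], "kind": ["night"]}
        )
        nonwear = [(0, 8640)]
        mask = acc.apply_sleep(st, sleep, nonwear)
        assert (mask == acc.NONWEAR).all()

    def test_partition_conservation(self, rng):
        """Every epoch gets exactly one label; counts sum to the total."""
        st = make_stream(rng.integers(0, 300, 4320))
        sleep = pd.DataFrame(
            {"child_id": ["c0001"], "start": ["2014-03-10 00:00:00"],
             "end": ["2014-03-10 06:00:00"], "kind": ["night"]}
        )
        nonwear = [(2000, 2300)]
        mask = acc.apply_sleep(st, sleep, nonwear)
        counts = [(mask == k).sum() for k in (acc.WORN_AWAKE, acc.WORN_ASLEEP, acc.NONWEAR)]
        assert sum(counts) == len(st)

    def test_overlapping_sleep_rejected(self):
        st = make_stream(np.full(60, 10))
        sleep = pd.DataFrame(
            {
                "child_id": ["c0001"] * 2,
                "start": ["2014-03-10 00:00:00", "2014-03-10 00:02:00"],
                "end": ["2014-03-10 00:05:00", "2014-03-10 00:06:00"],
                "kind": ["night", "night"],
            }
        )
        with pytest.raises(acc.EpochStreamError, match="overlap"):
            acc.apply_sleep(st, sleep, None)


def test_cutpoint_boundary():
    assert acc.classify_epoch(356)
    assert not acc.classify_epoch(357)
    assert acc.classify_epoch(0)


# ---------------------------------------------------------------------------
# day summaries
# ---------------------------------------------------------------------------

class TestSummarizeDays:
    def test_outcome_formula_reproduces_cohort_mean(self):
        """474.0 sedentary / 846.4 awake minutes -> 56.0% (one day built
        from counts on either side of the cut-point)."""
        n_sed = 4740 * 6 // 10  # 474.0 min of 10-s epochs
        n_act = int(round(846.4 * 6)) - n_sed
        x = np.r_[np.full(n_sed, 200), np.full(n_act, 1000)]
        st = make_stream(x, start="2014-03-10 06:00:00")
        days = acc.summarize_days(st, np.full(len(x), acc.WORN_AWAKE, dtype=np.int8))
        assert len(days) == 1
        row = days.iloc[0]
        assert row["sedentary_minutes"] == pytest.approx(474.0)
        assert row["awake_minutes"] == pytest.approx(846.33, abs=0.1)
        assert row["pct_sedentary"] == pytest.approx(56.0, abs=0.01)

    @pytest.mark.parametrize(
        "x_value, expected_pct", [(400, 0.0), (100, 100.0)]
    )
    def test_extreme_days(self, x_value, expected_pct):
        st = make_stream(np.full(600, x_value))
        days = acc.summarize_days(st, np.full(600, acc.WORN_AWAKE, dtype=np.int8))
        assert days["pct_sedentary"].iloc[0] == pytest.approx(expected_pct)

    def test_no_awake_time_flagged_invalid(self):
        st = make_stream(np.full(600, 10))
        days = acc.summarize_days(st, np.full(600, acc.WORN_ASLEEP, dtype=np.int8))
        assert np.isnan(days["pct_sedentary"].iloc[0])
        assert not days["valid_flag"].iloc[0]

    def test_day_boundary_at_midnight(self):
        st = make_stream(np.full(720, 10), start="2014-03-10 23:00:00")
        days = acc.summarize_days(st, np.full(720, acc.WORN_AWAKE, dtype=np.int8))
        assert list(days["date"]) == [pd.Timestamp("2014-03-10"), pd.Timestamp("2014-03-11")]
        assert days["awake_minutes"].tolist() == [60.0, 60.0]


# ---------------------------------------------------------------------------
# validity filter
# ---------------------------------------------------------------------------

def _days(child_id, specs):
    """specs: list of (date, awake_minutes)."""
    return pd.DataFrame(
        {
            "child_id": child_id,
            "date": [pd.Timestamp(d) for d, _ in specs],
            "awake_minutes": [m for _, m in specs],
            "sedentary_minutes": [m * 0.5 for _, m in specs],
            "pct_sedentary": 50.0,
            "weekday_flag": [pd.Timestamp(d).dayofweek < 5 for d, _ in specs],
            "school_day_flag": True,
            "valid_flag": True,
        }
    )


class TestFilterValid:
    def test_three_weekdays_one_weekend_retained(self):
        # Wed, Thu, Fri, Sat at 650 awake minutes
        days = _days("c1", [("2014-03-12", 650), ("2014-03-13", 650),
                            ("2014-03-14", 650), ("2014-03-15", 650)])
        kept = acc.filter_valid(days)
        assert len(kept) == 4

    def test_599_minute_day_dropped_before_counting(self):
        days = _days("c1", [("2014-03-12", 650), ("2014-03-13", 599),
                            ("2014-03-14", 650), ("2014-03-17", 650),
                            ("2014-03-15", 650)])
        kept = acc.filter_valid(days)
        assert len(kept) == 4
        assert pd.Timestamp("2014-03-13") not in set(kept["date"])

    def test_600_boundary_retained(self):
        days = _days("c1", [("2014-03-12", 600), ("2014-03-13", 650),
                            ("2014-03-14", 650), ("2014-03-15", 650)])
        assert len(acc.filter_valid(days)) == 4

    def test_no_weekend_day_excludes_child_entirely(self):
        days = _days("c1", [("2014-03-10", 700), ("2014-03-11", 700),
                            ("2014-03-12", 700), ("2014-03-13", 700),
                            ("2014-03-14", 700)])
        assert len(acc.filter_valid(days)) == 0

    def test_strict_profile_720_and_five_days(self):
        specs = [("2014-03-10", 730), ("2014-03-11", 730), ("2014-03-12", 730),
                 ("2014-03-13", 730), ("2014-03-14", 700)]
        days = _days("c1", specs)
        assert len(acc.filter_valid(days, profile="strict")) == 0  # only 4 days >= 720
        days2 = _days("c1", [(d, 730) for d, _ in specs])
        assert len(acc.filter_valid(days2, profile="strict")) == 5

    def test_idempotent(self):
        days = pd.concat(
            [
                _days("c1", [("2014-03-12", 650), ("2014-03-13", 650),
                             ("2014-03-14", 650), ("2014-03-15", 650)]),
                _days("c2", [("2014-03-12", 650), ("2014-03-13", 500),
                             ("2014-03-14", 650), ("2014-03-15", 650)]),
            ]
        )
        once = acc.filter_valid(days)
        twice = acc.filter_valid(once)
        pd.testing.assert_frame_equal(once, twice)
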