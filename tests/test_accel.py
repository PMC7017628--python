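"""Accelerometer processing: loading, reintegration, classification,
non-wear detection and daily/weekly summaries."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paq_agree.accel import (
    CutPoints,
    EpochSeries,
    NonwearParams,
    classify_intensity,
    classify_intensity_array,
    detect_nonwear,
    load_epochs,
    process_series,
    reintegrate,
    summarize_day,
    weekly_summary,
    write_epochs,
    INTENSITY_CATEGORIES,
)
from conftest import minutes


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadEpochs:
    def test_headerless_csv_preserves_row_count(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("\n".join(["100"] * 2880) + "\n")
        series = load_epochs(path, epoch_seconds=30)
        assert len(series) == 2880
        assert series.epoch_seconds == 30

    def test_device_header_declares_epoch_and_start(self, tmp_path):
        series = EpochSeries("P9", dt.datetime(2017, 5, 15, 8, 0), 30,
                             np.arange(100) % 200)
        path = tmp_path / "P9.csv"
        write_epochs(series, path)
        loaded = load_epochs(path)
        assert loaded.epoch_seconds == 30
        assert loaded.start_timestamp == dt.datetime(2017, 5, 15, 8, 0)
        assert np.array_equal(loaded.counts, series.counts)
        assert loaded.participant_id == "P9"

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("10\n-5\n3\n")
        with pytest.raises(ValueError, match="negative"):
            load_epochs(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("10\noops\n")
        with pytest.raises(ValueError, match=":2"):
            load_epochs(path)

    def test_timestamped_rows(self, tmp_path):
        path = tmp_path / "ts.csv"
        path.write_text("2017-05-15 00:00:00,150\n2017-05-15 00:01:00,20\n")
        series = load_epochs(path)
        assert list(series.counts) == [150, 20]


# ---------------------------------------------------------------------------
# reintegration
# ---------------------------------------------------------------------------

class TestReintegrate:
    def test_pairwise_sum(self):
        s = EpochSeries("x", dt.datetime(2017, 1, 1), 30, [100, 50, 0, 0])
        out = reintegrate(s, 60)
        assert list(out.counts) == [150, 0]
        assert out.epoch_seconds == 60

    def test_identity_on_minute_input(self):
        s = minutes([5, 10, 15])
        out = reintegrate(s, 60)
        assert list(out.counts) == [5, 10, 15]

    def test_trailing_partial_epoch_dropped(self):
        s = EpochSeries("x", dt.datetime(2017, 1, 1), 30, [1, 2, 3, 4, 5])
        out = reintegrate(s, 60)
        assert list(out.counts) == [3, 7]

    def test_shorter_target_rejected(self):
        s = minutes([1, 2])
        with pytest.raises(ValueError):
            reintegrate(s, 30)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 8000), min_size=2, max_size=50))
    def test_conservation_up_to_remainder(self, counts):
        s = EpochSeries("x", dt.datetime(2017, 1, 1), 30, counts)
        out = reintegrate(s, 60)
        kept = len(counts) // 2 * 2
        assert out.counts.sum() == sum(counts[:kept])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassify:
    @pytest.mark.parametrize("cpm,expected", [
        (0, "sedentary"), (99, "sedentary"), (100, "light"), (1951, "light"),
        (1952, "moderate"), (5724, "moderate"), (5725, "vigorous"), (20000, "vigorous"),
    ])
    def test_band_edges(self, cpm, expected):
        assert classify_intensity(cpm) == expected

    def test_totality_every_cpm_gets_one_category(self):
        codes = classify_intensity_array(np.arange(0, 10001))
        assert codes.min() >= 0 and codes.max() <= 3
        # category counts match the band widths
        assert (codes == 0).sum() == 100
        assert (codes == 1).sum() == 1951 - 100 + 1
        assert (codes == 2).sum() == 5724 - 1952 + 1

    def test_custom_cutpoints(self):
        cuts = CutPoints(10, 20, 30)
        assert classify_intensity(15, cuts) == "light"
        assert classify_intensity(31, cuts) == "vigorous"

    def test_invalid_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            CutPoints(100, 50, 30)

    def test_negative_cpm_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(-1)


# ---------------------------------------------------------------------------
# non-wear detection
# ---------------------------------------------------------------------------

class TestDetectNonwear:
    def test_pure_zero_run_marked(self):
        mask = detect_nonwear(minutes([0] * 120))
        assert mask.all()

    def test_window_below_threshold_is_wear(self):
        mask = detect_nonwear(minutes([0] * 59 + [500]))
        assert not mask.any()

    def test_sixty_zero_minutes_is_nonwear(self):
        mask = detect_nonwear(minutes([0] * 60 + [500]))
        assert mask[:60].all() and not mask[60]

    def test_two_minute_interruption_absorbed(self):
        mask = detect_nonwear(minutes([0] * 30 + [50, 50] + [0] * 40))
        assert mask.all()  # all 72 minutes belong to the window

    def test_three_minute_interruption_breaks_window(self):
        mask = detect_nonwear(minutes([0] * 30 + [50, 50, 50] + [0] * 40))
        assert not mask.any()

    def test_interruption_above_100_cpm_breaks_window(self):
        mask = detect_nonwear(minutes([0] * 30 + [150] + [0] * 40))
        assert not mask.any()

    def test_trailing_interruption_not_marked(self):
        seq = [0] * 60 + [50] + [500] * 10
        mask = detect_nonwear(minutes(seq))
        assert mask[:60].all()
        assert not mask[60:].any()

    def test_requires_minute_epochs(self):
        s = EpochSeries("x", dt.datetime(2017, 1, 1), 30, [0] * 200)
        with pytest.raises(ValueError, match="per-minute"):
            detect_nonwear(s)

    def test_matches_brute_force_oracle_on_random_sequences(self, nonwear_oracle):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 301))
            # zero-inflated counts so long zero runs actually occur
            x = np.where(rng.random(n) < 0.6, 0,
                         rng.integers(1, 300, size=n)).astype(np.int64)
            got = detect_nonwear(minutes(x))
            want = nonwear_oracle(x)
            assert np.array_equal(got, want), x.tolist()

    def test_interruption_cap_zero_tolerates_nothing(self):
        params = NonwearParams(max_interruption_runs_per_window=0)
        seq = [0] * 30 + [50] + [0] * 40
        assert not detect_nonwear(minutes(seq), params).any()
        assert detect_nonwear(minutes([0] * 60), params).all()

    def test_interruption_cap_one_limits_windows(self):
        params = NonwearParams(max_interruption_runs_per_window=1)
        # two interruptions: only a one-interruption sub-window can qualify
        seq = [0] * 30 + [50] + [0] * 30 + [50] + [0] * 10
        mask = detect_nonwear(minutes(seq), params)
        assert mask[:61].all()      # first window: 30 zeros + 1 int + 30 zeros
        assert not mask[62:].any()  # remaining fragment alone is too short


# ---------------------------------------------------------------------------
# day and week summaries
# ---------------------------------------------------------------------------

class TestSummaries:
    def test_constructed_day(self):
        seq = [0] * 480 + [50] * 600 + [500] * 240 + [3000] * 100 + [6000] * 20
        s = minutes(seq)
        mask = detect_nonwear(s)
        day = summarize_day(s, mask)
        assert day.recorded_minutes == 1440
        assert day.nonwear_minutes == 480
        assert day.wear_minutes == 960
        assert (day.sedentary_minutes, day.light_minutes,
                day.moderate_minutes, day.vigorous_minutes) == (600, 240, 100, 20)
        assert day.valid

    def test_wear_below_ten_hours_invalid(self):
        seq = [500] * 599 + [0] * 841
        s = minutes(seq)
        day = summarize_day(s, detect_nonwear(s))
        assert day.wear_minutes == 599
        assert not day.valid

    def test_all_zero_day(self):
        s = minutes([0] * 1440)
        day = summarize_day(s, detect_nonwear(s))
        assert day.wear_minutes == 0
        assert day.sedentary_minutes == 0
        assert not day.valid

    def test_conservation_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = np.where(rng.random(1440) < 0.5, 0, rng.integers(1, 7000, size=1440))
            s = minutes(x)
            day = summarize_day(s, detect_nonwear(s))
            total_cat = (day.sedentary_minutes + day.light_minutes
                         + day.moderate_minutes + day.vigorous_minutes)
            assert total_cat == day.wear_minutes
            assert day.wear_minutes + day.nonwear_minutes == day.recorded_minutes

    def test_adding_nonwear_block_never_increases_categories(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 4000, size=600)
        s = minutes(x)
        base = summarize_day(s, detect_nonwear(s))
        extended = minutes(list(x) + [0] * 120)
        more = summarize_day(extended, detect_nonwear(extended))
        for attr in ("sedentary_minutes", "light_minutes",
                     "moderate_minutes", "vigorous_minutes"):
            assert getattr(more, attr) <= getattr(base, attr)

    def test_weekly_average_over_valid_days(self):
        def day(mod, valid=True):
            wear = 700 if valid else 300
            from paq_agree.accel import DayMetrics
            return DayMetrics("p", dt.date(2017, 5, 15), 1440, wear, 1440 - wear,
                              wear - mod, 0, mod, 0, valid)

        week = weekly_summary([day(30), day(60), day(90)], week_index=1)
        assert week.moderate_min_per_day == 60
        assert week.usable

        week2 = weekly_summary([day(30), day(60), day(90, valid=False)], 1)
        assert week2.n_valid_days == 2
        assert not week2.usable
        assert week2.moderate_min_per_day == 45  # still reported, flagged

    def test_zero_vigorous_average(self):
        from paq_agree.accel import DayMetrics
        days = [DayMetrics("p", dt.date(2017, 5, 15 + i), 1440, 700, 740,
                           700, 0, 0, 0, True) for i in range(7)]
        week = weekly_summary(days, 1)
        assert week.vigorous_min_per_day == 0
        assert week.usable

    def test_empty_week_rejected(self):
        with pytest.raises(ValueError):
            weekly_summary([], 1)

    def test_process_series_splits_weeks(self, small_study):
        pid = small_study.roster[0].participant_id
        days, weeks = process_series(small_study.epochs[pid])
        assert len(days) == 14
        assert [w.week_index for w in weeks] == [1, 2]
        assert all(w.n_days == 7 for w in weeks)
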