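"""Windowed profiling, stage summaries, dip detection, transition-day stats."""

import numpy as np
import pandas as pd
import pytest

from electrome import (
    ApEnParams,
    ApEnProfile,
    InvalidInputError,
    RipeningTrajectory,
    WindowResult,
    concat_profiles,
    detect_dip,
    profile_from_frame,
    profile_to_frame,
    stage_summary,
    transition_days_summary,
    windowed_apen,
)
from conftest import make_series


def profile_from_values(values, fruit_id="f", window_s=30.0, day0=0.0):
    """Hand-built profile: one window per value, back to back in time."""
    windows = tuple(
        WindowResult(
            start_s=day0 * 86400.0 + i * window_s,
            end_s=day0 * 86400.0 + (i + 1) * window_s,
            n_samples=64,
            r_absolute=1.0,
            apen=float(v),
        )
        for i, v in enumerate(values)
    )
    return ApEnProfile(fruit_id=fruit_id, windows=windows, params=ApEnParams(),
                       window_len_samples=64, step_samples=64)


class TestWindowedApen:
    def test_window_count_conservation(self, rng):
        s = make_series(rng.normal(size=10 * 128))
        prof = windowed_apen(s, window_len_samples=128)
        assert len(prof.windows) == 10
        # overlapping windows: floor((N - w)/step) + 1
        prof2 = windowed_apen(s, window_len_samples=128, step_samples=50)
        assert len(prof2.windows) == (10 * 128 - 128) // 50 + 1

    def test_constant_series_all_zero(self):
        prof = windowed_apen(make_series(np.ones(512)), window_len_samples=128)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_noise_block_above_periodic_block(self, rng):
        noise = rng.uniform(0, 1, 512)
        periodic = np.tile([0.0, 1.0], 256)
        prof = windowed_apen(make_series(np.concatenate([noise, periodic])),
                             window_len_samples=128)
        first, second = prof.values[:4], prof.values[4:]
        assert first.min() > second.max()

    def test_per_window_tolerance(self, rng):
        # amplitude step between windows -> per-window r differs
        x = np.concatenate([rng.normal(size=128), 100.0 * rng.normal(size=128)])
        prof = windowed_apen(make_series(x), window_len_samples=128)
        r = [w.r_absolute for w in prof.windows]
        assert r[1] > 10 * r[0]

    def test_window_times(self, rng):
        s = make_series(rng.normal(size=256), fs=64.0, t0=100.0)
        prof = windowed_apen(s, window_len_samples=128)
        assert prof.windows[0].start_s == 100.0
        assert prof.windows[0].end_s == pytest.approx(102.0)
        assert prof.windows[1].start_s == pytest.approx(102.0)

    def test_too_short_series(self, rng):
        with pytest.raises(InvalidInputError, match="shorter than one window"):
            windowed_apen(make_series(rng.normal(size=100)), window_len_samples=128)

    def test_round_trip_through_frame(self, rng):
        prof = windowed_apen(make_series(rng.normal(size=512), fruit_id="f1"),
                             window_len_samples=128)
        back = profile_from_frame(profile_to_frame(prof))
        assert len(back) == 1
        assert back[0].windows == prof.windows
        assert back[0].step_samples == prof.step_samples


class TestConcat:
    def test_orders_by_time(self, rng):
        p1 = profile_from_values([1.0, 2.0], day0=1.0)
        p0 = profile_from_values([3.0, 4.0], day0=0.0)
        merged = concat_profiles([p1, p0])
        assert [w.apen for w in merged.windows] == [3.0, 4.0, 1.0, 2.0]

    def test_rejects_mixed_fruits(self):
        with pytest.raises(InvalidInputError):
            concat_profiles([profile_from_values([1.0], "a"), profile_from_values([1.0], "b")])


class TestStageSummary:
    def test_single_stage_constant(self):
        prof = profile_from_values([0.0] * 6)
        trajs = {"f": RipeningTrajectory("f", (("MG", 0, 1),))}
        summ = stage_summary([prof], trajs)
        row = summ.table.iloc[0]
        assert (row.stage, row.mean_apen, row.sd_apen) == ("MG", 0.0, 0.0)
        assert row.n_windows == 6 and row.n_fruits == 1
        assert summ.n_unassigned == 0

    def test_windows_assigned_by_midpoint_day(self):
        values = [1.0, 2.0, 3.0]
        # one window per day: days 0, 1, 2
        windows = tuple(
            WindowResult(d * 86400.0, d * 86400.0 + 30.0, 64, 1.0, v)
            for d, v in enumerate(values)
        )
        prof = ApEnProfile("f", windows, ApEnParams(), 64, 64)
        trajs = {"f": RipeningTrajectory("f", (("MG", 0, 1), ("B", 1, 2)))}
        summ = stage_summary([prof], trajs)
        table = summ.table.set_index("stage")
        assert table.loc["MG", "mean_apen"] == 1.0
        assert table.loc["B", "mean_apen"] == 2.0
        assert summ.n_unassigned == 1  # day-2 window past the trajectory end

    def test_permutation_invariant_in_fruit_order(self):
        profs = [profile_from_values([1.0, 2.0], "a"), profile_from_values([5.0, 7.0], "b")]
        trajs = {k: RipeningTrajectory(k, (("MG", 0, 1),)) for k in ("a", "b")}
        t1 = stage_summary(profs, trajs).table
        t2 = stage_summary(profs[::-1], trajs).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_profile_list_is_error(self):
        with pytest.raises(InvalidInputError):
            stage_summary([], {})

    def test_missing_trajectory_is_error(self):
        with pytest.raises(InvalidInputError, match="no trajectory"):
            stage_summary([profile_from_values([1.0], "ghost")], {})


class TestDetectDip:
    def test_v_shape_minimum(self):
        prof = profile_from_values([5, 4, 3, 2, 3, 4, 5])
        report = detect_dip(prof, smooth_k=1)
        assert report.dip_window == (prof.windows[3].start_s, prof.windows[3].end_s)
        assert report.dip_value == 2.0
        assert report.pre_dip_median == 4.0
        assert report.post_dip_median == 4.0

    def test_monotone_decreasing_boundary(self):
        prof = profile_from_values([7, 6, 5, 4, 3, 2])
        report = detect_dip(prof, smooth_k=1)
        assert report.dip_window == (prof.windows[-1].start_s, prof.windows[-1].end_s)
        assert report.post_dip_median is None

    def test_tie_broken_earliest(self):
        prof = profile_from_values([3, 1, 2, 1, 3, 3])
        report = detect_dip(prof, smooth_k=1)
        assert report.dip_window[0] == prof.windows[1].start_s

    def test_dip_bounded_by_medians(self, rng):
        prof = profile_from_values(rng.uniform(0, 2, 30))
        report = detect_dip(prof, smooth_k=5)
        if report.pre_dip_median is not None:
            assert report.dip_value <= report.pre_dip_median
        if report.post_dip_median is not None:
            assert report.dip_value <= report.post_dip_median

    def test_smoothing_resists_outlier(self):
        # a single spiked-low window must not set the dip location
        values = [5.0] * 10 + [0.0] + [5.0] * 10 + [2.0, 2.0, 2.0, 2.0, 2.0]
        report = detect_dip(profile_from_values(values), smooth_k=5)
        assert report.dip_window[0] >= profile_from_values(values).windows[21].start_s

    def test_stage_attribution(self):
        prof = profile_from_values([5, 4, 1, 4, 5, 5], window_s=86400.0)  # one window/day
        traj = RipeningTrajectory("f", (("MG", 0, 2), ("B", 2, 4), ("LR", 4, 6)))
        assert detect_dip(prof, 1, traj).dip_in_stage == "B"

    def test_parameter_validation(self):
        prof = profile_from_values([1, 2, 3, 4])
        with pytest.raises(InvalidInputError):
            detect_dip(prof, smooth_k=4)
        with pytest.raises(InvalidInputError, match="windows"):
            detect_dip(prof, smooth_k=5)


class TestTransitionDays:
    def test_single_fruit(self):
        trajs = {"f": RipeningTrajectory("f", (("MG", 0, 3), ("B", 3, 5)))}
        table = transition_days_summary(trajs).set_index("transition")
        assert table.loc["MG->B", "mean_days"] == 3.0
        assert table.loc["MG->B", "sd_days"] == 0.0

    def test_two_fruits_population_sd(self):
        trajs = {
            "a": RipeningTrajectory("a", (("MG", 0, 2), ("B", 2, 4))),
            "b": RipeningTrajectory("b", (("MG", 0, 4), ("B", 4, 6))),
        }
        table = transition_days_summary(trajs).set_index("transition")
        assert table.loc["MG->B", "mean_days"] == 3.0
        assert table.loc["MG->B", "sd_days"] == 1.0
        assert table.loc["MG->B", "n_fruits"] == 2

    def test_empty_is_error(self):
        with pytest.raises(InvalidInputError):
            transition_days_summary({})
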