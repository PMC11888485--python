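"""Gaze pipeline: alignment, blinks, drift correction, and Results metrics."""

import math

import numpy as np
import pytest

from crowdfix import (GazeTrace, align_gaze_to_frames, classify_abnormal_bouma,
                      count_breaks, cursor_error, detect_blinks,
                      drift_correct_trial, relative_rmse, remove_blinks,
                      rmse_per_timepoint, summarize_group, sweep_breaks)
from crowdfix.gaze import TrialUnusableError, round_percent

from conftest import make_aligned_trial

DT = 1.0 / 60.0


def make_trace(times, xy):
    return GazeTrace(times=np.asarray(times, float),
                     xy=np.asarray(xy, float))


class TestAlignment:
    def _frames(self, n=60, t0=1000.0):
        times = t0 + DT * np.arange(n)
        phases = np.array(["track"] * (n - 10) + ["view"] * 10, dtype=object)
        ch = np.zeros((n, 2))
        cur = np.zeros((n, 2))
        return times, phases, ch, cur

    def test_constant_gaze_interpolates_to_constant(self):
        times, phases, ch, cur = self._frames()
        gt = np.arange(times[0] - 0.1, times[-1] + 0.1, 0.01)
        trace = make_trace(gt, np.tile([1.5, -0.5], (len(gt), 1)))
        out = align_gaze_to_frames(times, phases, ch, cur, trace, times[-10])
        np.testing.assert_allclose(out.gaze, np.tile([1.5, -0.5],
                                                     (len(times), 1)))
        assert out.valid.all()

    def test_linear_ramp_interpolated_exactly(self):
        times, phases, ch, cur = self._frames()
        gt = np.arange(times[0] - 0.05, times[-1] + 0.05, 0.01)  # 100 Hz
        ramp = np.column_stack([2.0 * (gt - gt[0]), -1.0 * (gt - gt[0])])
        trace = make_trace(gt, ramp)
        out = align_gaze_to_frames(times, phases, ch, cur, trace, times[-10])
        expect = np.column_stack([2.0 * (times - gt[0]),
                                  -1.0 * (times - gt[0])])
        np.testing.assert_allclose(out.gaze, expect, atol=1e-10)

    def test_clock_offset_recovered_within_half_sample(self):
        # one stream shifted by 12.3 ms: POSIX alignment plus linear
        # interpolation must reproduce the underlying signal at frame times
        times, phases, ch, cur = self._frames()
        offset = 0.0123
        gt = np.arange(times[0] - 0.05, times[-1] + 0.05, 0.01) + offset
        sig = np.column_stack([np.sin(0.7 * gt), np.cos(0.7 * gt)])
        trace = make_trace(gt, sig)
        out = align_gaze_to_frames(times, phases, ch, cur, trace, times[-10])
        truth = np.column_stack([np.sin(0.7 * times), np.cos(0.7 * times)])
        worst = np.abs(out.gaze - truth).max()
        assert worst < 0.7 * 0.005  # signal slope x half a gaze sample period

    def test_disjoint_ranges_rejected(self):
        times, phases, ch, cur = self._frames()
        trace = make_trace([0.0, 1.0], [[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            align_gaze_to_frames(times, phases, ch, cur, trace, times[-10])


class TestBlinkDetection:
    def _pursuit_trace(self, n=200, rate=100.0):
        t = 1000.0 + np.arange(n) / rate
        xy = np.column_stack([0.5 * np.cos(0.8 * t), 0.5 * np.sin(0.8 * t)])
        return make_trace(t, xy), xy  # crosshair ref == gaze (clean pursuit)

    def test_clean_pursuit_no_blinks(self):
        trace, ch = self._pursuit_trace()
        assert detect_blinks(trace, ch) == []

    def test_large_excursion_flagged_once(self):
        trace, ch = self._pursuit_trace()
        xy = trace.xy.copy()
        xy[100] += [0.0, -25.0]  # 25-deg single-sample excursion
        trace = make_trace(trace.times, xy)
        blinks = detect_blinks(trace, ch)
        assert len(blinks) == 1
        b = blinks[0]
        assert b.start_time <= trace.times[100] <= b.end_time
        assert b.padded_start == pytest.approx(b.start_time - 0.1)
        assert b.padded_end == pytest.approx(b.end_time + 0.1)

    def test_sub_threshold_excursion_ignored(self):
        # 19-deg deviation approached at 999 deg/s: both criteria below limits
        rate = 100.0
        t = 1000.0 + np.arange(600) / rate
        x = np.zeros(len(t))
        ramp = slice(100, 100 + int(19.0 / (999.0 / rate)) + 1)
        n_ramp = ramp.stop - ramp.start
        x[ramp] = np.minimum(999.0 * np.arange(n_ramp) / rate, 19.0)
        x[ramp.stop:] = 19.0
        trace = make_trace(t, np.column_stack([x, np.zeros_like(x)]))
        assert detect_blinks(trace, np.zeros((len(t), 2))) == []

    def test_nearby_blinks_merge_after_padding(self):
        trace, ch = self._pursuit_trace(n=400)
        xy = trace.xy.copy()
        xy[100] += [0.0, -25.0]
        xy[110] += [0.0, -25.0]  # 0.1 s later: padded intervals overlap
        trace = make_trace(trace.times, xy)
        blinks = detect_blinks(trace, ch)
        assert len(blinks) == 1
        assert blinks[0].start_time <= trace.times[100]
        assert blinks[0].end_time >= trace.times[110]


class TestBlinkRemoval:
    def _trial(self, n=120):
        return make_aligned_trial([("track", n - 19, 0.0), ("view", 9, 0.0),
                                   ("respond", 10, 0.0)])

    def test_no_blinks_is_identity(self):
        tr = self._trial()
        out = remove_blinks(tr, [])
        np.testing.assert_array_equal(out.gaze, tr.gaze)

    def test_mid_trial_blink_replaced_with_post_blink_sample(self):
        tr = self._trial()
        tr.gaze[:, 0] = np.arange(len(tr.times)) * 0.01  # recognizable ramp
        from crowdfix import BlinkInterval
        t0 = tr.times[0]
        b = BlinkInterval(start_time=t0 + 0.5, end_time=t0 + 0.6,
                          padded_start=t0 + 0.4, padded_end=t0 + 0.7,
                          replacement_source_time=t0 + 0.8)
        out = remove_blinks(tr, [b])
        mask = (tr.times >= b.padded_start) & (tr.times <= b.padded_end)
        src_idx = int(np.argmin(np.abs(tr.times - (t0 + 0.8))))
        np.testing.assert_allclose(out.gaze[mask],
                                   np.tile(tr.gaze[src_idx], (mask.sum(), 1)))
        np.testing.assert_array_equal(out.gaze[~mask], tr.gaze[~mask])
        # idempotent
        again = remove_blinks(out, [b])
        np.testing.assert_array_equal(again.gaze, out.gaze)

    def test_end_of_trial_blink_uses_pre_blink_sample(self):
        tr = self._trial()
        tr.gaze[:, 0] = np.arange(len(tr.times)) * 0.01
        from crowdfix import BlinkInterval
        t1 = tr.times[-1]
        b = BlinkInterval(start_time=t1 - 0.2, end_time=t1 - 0.05,
                          padded_start=t1 - 0.3, padded_end=t1 + 0.05,
                          replacement_source_time=t1 + 0.15)
        out = remove_blinks(tr, [b])
        mask = tr.times >= b.padded_start
        src_idx = int(np.argmin(np.abs(tr.times - (b.padded_start - 0.1))))
        np.testing.assert_allclose(out.gaze[mask],
                                   np.tile(tr.gaze[src_idx], (mask.sum(), 1)))

    def test_blink_spanning_trial_marks_unusable(self):
        tr = self._trial()
        from crowdfix import BlinkInterval
        b = BlinkInterval(start_time=tr.times[0], end_time=tr.times[-1],
                          padded_start=tr.times[0] - 0.1,
                          padded_end=tr.times[-1] + 0.1,
                          replacement_source_time=tr.times[-1] + 0.2)
        with pytest.raises(TrialUnusableError):
            remove_blinks(tr, [b])


class TestDriftCorrection:
    def test_constant_offset_cancels_exactly(self, trial_factory):
        tr = trial_factory([("track", 60, 0.7), ("view", 9, 0.7),
                            ("respond", 10, 0.7)])
        out = drift_correct_trial(tr)
        np.testing.assert_allclose(out.deviation, 0.0, atol=1e-12)
        assert out.drift_corrected

    def test_zero_offset_is_identity(self, trial_factory):
        tr = trial_factory([("track", 60, 0.0), ("view", 9, 0.0)])
        out = drift_correct_trial(tr)
        np.testing.assert_allclose(out.gaze, tr.gaze, atol=1e-15)

    def test_linear_ramp_zero_mean_over_terminal_window(self, trial_factory):
        slope = 0.02  # deg per frame
        tr = trial_factory([("track", 90, lambda k: [slope * k, 0.0]),
                            ("view", 9, lambda k: [slope * k, 0.0])])
        out = drift_correct_trial(tr)
        track = out.phase == "track"
        t_track = out.times[track]
        win = track & (out.times > t_track[-1] - 0.4 + 1e-12)
        dev = out.gaze - out.crosshair
        np.testing.assert_allclose(dev[win].mean(axis=0), [0.0, 0.0],
                                   atol=1e-10)
        # earlier frames shifted by the window mean of the ramp
        k_win = np.flatnonzero(win)
        expected_shift = slope * np.mean(k_win)
        np.testing.assert_allclose(dev[0], [slope * 0 - expected_shift, 0.0],
                                   atol=1e-10)

    def test_short_track_phase_rejected(self, trial_factory):
        tr = trial_factory([("track", 20, 0.0), ("view", 9, 0.0)])
        with pytest.raises(TrialUnusableError):
            drift_correct_trial(tr)


class TestRmse:
    def test_constant_deviation_curve(self, trial_factory):
        trials = [trial_factory([("track", 30, 1.0), ("view", 9, 1.0)])
                  for _ in range(5)]
        curve = rmse_per_timepoint(trials)
        np.testing.assert_allclose(curve.rmse, 1.0, atol=1e-12)

    def test_two_trial_closed_form(self, trial_factory):
        t1 = trial_factory([("track", 30, 0.0), ("view", 9, 0.0)])
        t2 = trial_factory([("track", 30, 2.0), ("view", 9, 2.0)])
        curve = rmse_per_timepoint([t1, t2], min_fraction=1.0)
        np.testing.assert_allclose(curve.rmse, math.sqrt(2.0), atol=1e-12)

    def test_matches_bruteforce_oracle(self, trial_factory, rng):
        trials = []
        for _ in range(6):
            dev = rng.normal(0, 1, size=(39, 2))
            trials.append(trial_factory([("track", 30, dev[:30]),
                                         ("view", 9, dev[30:])]))
        curve = rmse_per_timepoint(trials, min_fraction=1.0)
        # oracle: explicit loop over aligned frame offsets
        for i, t in enumerate(curve.time):
            devs = []
            for tr in trials:
                k = int(round((t - (tr.time_from_view_onset[0])) / DT))
                devs.append(tr.deviation[k])
            assert curve.rmse[i] == pytest.approx(
                math.sqrt(np.mean(np.square(devs))), abs=1e-10)

    def test_relative_ratio(self, trial_factory):
        half = [trial_factory([("track", 30, 0.5), ("view", 9, 0.5)])
                for _ in range(3)]
        ref = [trial_factory([("track", 30, 1.0), ("view", 9, 1.0)])
               for _ in range(3)]
        ratio = relative_rmse(rmse_per_timepoint(half),
                              rmse_per_timepoint(ref))
        np.testing.assert_allclose(ratio.rmse, 0.5, atol=1e-12)
        same = relative_rmse(rmse_per_timepoint(ref), rmse_per_timepoint(ref))
        np.testing.assert_allclose(same.rmse, 1.0, atol=1e-12)


class TestBreaks:
    def _trials(self, n_exceed, n_total, amplitude=2.0):
        trials = []
        for i in range(n_total):
            dev = amplitude if i < n_exceed else 0.2
            trials.append(make_aligned_trial([("track", 30, 0.1),
                                              ("view", 9, dev)]))
        return trials

    def test_six_of_seventy_prints_nine_percent(self):
        trials = self._trials(6, 70)
        count, pct = count_breaks(trials, tolerance=1.5)
        assert count == 6
        assert pct == pytest.approx(100 * 6 / 70)
        assert round_percent(pct) == 9

    def test_track_deviation_alone_does_not_break(self):
        trials = [make_aligned_trial([("track", 30, 5.0), ("view", 9, 0.0)])]
        assert count_breaks(trials, 1.5) == (0, 0.0)
        assert count_breaks(trials, 1.5, include_track=True) == (1, 100.0)

    def test_sweep_monotone_and_matches_single_counts(self, rng):
        trials = [make_aligned_trial(
            [("track", 30, 0.1), ("view", 9, float(rng.uniform(0, 3)))])
            for _ in range(40)]
        tols = [0.0, 0.5, 1.0, 1.5, 2.0, 3.5]
        sweep = sweep_breaks(trials, tols)
        assert np.all(np.diff(sweep.break_percent) <= 0)
        for tol, pct in zip(tols, sweep.break_percent):
            assert pct == count_breaks(trials, tol)[1]
        assert sweep.break_percent[0] == 100.0  # all nonzero deviations break


class TestCursorError:
    def test_glued_cursor_zero(self, trial_factory):
        tr = trial_factory([("track", 30, 0.0), ("view", 9, 0.0)])
        assert cursor_error([tr]) == 0.0

    def test_constant_offset(self, trial_factory):
        tr = trial_factory([("track", 30, 0.0), ("view", 9, 0.0)],
                           cursor_offset=[0.1, 0.0])
        assert cursor_error([tr]) == pytest.approx(0.1, abs=1e-12)

    def test_matches_bruteforce_oracle(self, trial_factory, rng):
        trials = []
        for _ in range(4):
            off = rng.normal(0, 0.1, size=(39, 2))
            trials.append(trial_factory([("track", 30, 0.0), ("view", 9, 0.0)],
                                        cursor_offset=off))
        sq = []
        for tr in trials:
            for k in range(len(tr.times)):
                if tr.phase[k] == "track":
                    sq.append(np.sum((tr.cursor[k] - tr.crosshair[k]) ** 2))
        assert cursor_error(trials) == pytest.approx(
            math.sqrt(np.mean(sq)), abs=1e-10)


class TestBoumaScreening:
    @pytest.mark.parametrize("b,expected", [
        (0.095, True), (0.2, False), (0.096, False),
    ])
    def test_strict_cutoff_convention(self, b, expected):
        assert classify_abnormal_bouma(b) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_abnormal_bouma(0.0)


class TestGroupSummary:
    def test_geometric_mean_examples(self, rng):
        est, lo, hi = summarize_group([1.0, 4.0], rng, n_boot=200)
        assert est == pytest.approx(2.0, abs=1e-12)
        est, lo, hi = summarize_group([3.0] * 8, rng, n_boot=200)
        assert est == lo == hi == pytest.approx(3.0)

    def test_nonpositive_rejected(self, rng):
        with pytest.raises(ValueError):
            summarize_group([1.0, -2.0], rng)

    def test_bootstrap_ci_coverage_on_lognormal(self):
        # 68% interval for the geometric mean should cover the true value
        # about 68% of the time (percentile bootstrap coverage is nominal
        # for groups large enough that its small-sample bias is negligible)
        rng = np.random.default_rng(99)
        true_gm = math.exp(0.3)
        hits = 0
        n_rep = 600
        for _ in range(n_rep):
            data = np.exp(rng.normal(0.3, 0.5, size=40))
            _, lo, hi = summarize_group(data, rng, n_boot=300)
            hits += lo <= true_gm <= hi
        assert abs(hits / n_rep - 0.68) < 0.05
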