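"""Gaze-analysis pipeline: alignment, blink removal, drift correction, metrics.

The experiment program logs crosshair/cursor position per 60-Hz frame; the
eye tracker logs gaze position on its own clock (100 Hz by default).  Both
carry POSIX timestamps, which are used to align the streams.  Per trial the
pipeline then:

1. interpolates gaze onto the frame timestamps (:func:`align_gaze_to_frames`);
2. detects blinks on the native-rate gaze stream — samples whose speed
   exceeds 1000 deg/s or whose distance from the crosshair exceeds 20 deg —
   pads each blink by 100 ms on both sides and replaces the padded span with
   the gaze position recorded 100 ms after it (100 ms before it for blinks
   at the end of a trial);
3. removes slow eye-tracker calibration drift by subtracting the mean
   gaze-minus-crosshair deviation over the last 400 ms of the Track phase
   from the deviation at every frame of the trial.

On the cleaned trials it computes the metrics used to compare fixation
tasks: the RMSE gaze-to-crosshair distance across trials at each within-
trial timepoint (and its ratio to a stationary-fixation reference), the
percentage of trials whose View-interval deviation exceeds a fixation-break
tolerance (swept over tolerances), RMS cursor tracking error, Bouma-factor
abnormality screening against the 0.096 minimum plausible value, and
geometric-mean group summaries with 68% bootstrap confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GazeTrace",
    "AlignedTrial",
    "BlinkInterval",
    "BreakSweep",
    "RmseCurve",
    "TrialUnusableError",
    "align_gaze_to_frames",
    "detect_blinks",
    "remove_blinks",
    "drift_correct_trial",
    "rmse_per_timepoint",
    "relative_rmse",
    "count_breaks",
    "sweep_breaks",
    "cursor_error",
    "classify_abnormal_bouma",
    "summarize_group",
    "round_percent",
]

BLINK_SPEED_THRESHOLD = 1000.0   # deg/s
BLINK_DEVIATION_THRESHOLD = 20.0  # deg from the crosshair
BLINK_PAD = 0.100                 # s on each side of a detected blink
DRIFT_WINDOW = 0.400              # s at the end of the Track phase
ABNORMAL_BOUMA_CUTOFF = 0.096     # minimum plausible Bouma factor at 10 deg


class TrialUnusableError(ValueError):
    """Raised when a trial cannot be cleaned (e.g. a blink spans all of it)."""


@dataclass
class GazeTrace:
    """Native-rate eye-tracker samples (times strictly increasing)."""

    times: np.ndarray        # (n,) POSIX s
    xy: np.ndarray           # (n, 2) deg
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("gaze timestamps must be strictly increasing")


@dataclass
class AlignedTrial:
    """One trial's frame-aligned crosshair/cursor/gaze streams."""

    times: np.ndarray          # (n,) POSIX s, frame clock
    phase: np.ndarray          # (n,) str: track | view | respond
    crosshair: np.ndarray      # (n, 2) deg
    cursor: np.ndarray         # (n, 2) deg, NaN when hidden
    gaze: np.ndarray           # (n, 2) deg
    valid: np.ndarray          # (n,) bool, gaze coverage
    view_onset: float          # POSIX s of the first View frame
    drift_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.crosshair = np.asarray(self.crosshair, dtype=float).reshape(-1, 2)
        self.cursor = np.asarray(self.cursor, dtype=float).reshape(-1, 2)
        self.gaze = np.asarray(self.gaze, dtype=float).reshape(-1, 2)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def deviation(self) -> np.ndarray:
        """Euclidean gaze-to-crosshair distance per frame, deg."""
        return np.linalg.norm(self.gaze - self.crosshair, axis=1)

    @property
    def time_from_view_onset(self) -> np.ndarray:
        return self.times - self.view_onset


@dataclass(frozen=True)
class BlinkInterval:
    start_time: float
    end_time: float
    padded_start: float
    padded_end: float
    replacement_source_time: float

    def __post_init__(self) -> None:
        if self.start_time > self.end_time:
            raise ValueError("blink start must not exceed end")


@dataclass
class BreakSweep:
    tolerances: np.ndarray
    break_percent: np.ndarray
    break_count: np.ndarray
    n_trials: int


@dataclass
class RmseCurve:
    """RMSE across trials per within-trial frame offset from View onset."""

    time: np.ndarray     # s from View onset
    rmse: np.ndarray     # deg
    n: np.ndarray        # trials contributing per timepoint


def align_gaze_to_frames(frame_times, phases, crosshair, cursor,
                         gaze: GazeTrace, view_onset: float) -> AlignedTrial:
    """Linearly interpolate the gaze stream onto the frame clock.

    Frames outside the gaze stream's time coverage are marked invalid.
    Raises ValueError if the two streams do not overlap at all.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times[-1] < gaze.times[0] or frame_times[0] > gaze.times[-1]:
        raise ValueError("frame log and gaze trace cover disjoint time ranges")
    gx = np.interp(frame_times, gaze.times, gaze.xy[:, 0])
    gy = np.interp(frame_times, gaze.times, gaze.xy[:, 1])
    valid = (frame_times >= gaze.times[0]) & (frame_times <= gaze.times[-1])
    return AlignedTrial(times=frame_times, phase=np.asarray(phases, dtype=object),
                        crosshair=crosshair, cursor=cursor,
                        gaze=np.column_stack([gx, gy]), valid=valid,
                        view_onset=view_onset)


def _merge_intervals(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    spans = sorted(spans)
    merged: list[tuple[float, float]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def detect_blinks(trace: GazeTrace, crosshair_ref) -> list[BlinkInterval]:
    """Flag blink samples on the native gaze stream and merge into intervals.

    A sample is part of a blink when its central-finite-difference speed
    exceeds 1000 deg/s or its distance from the crosshair exceeds 20 deg.
    ``crosshair_ref`` is either an (n, 2) array of crosshair positions at
    the gaze sample times or a callable mapping times to positions.
    Padded (+/-100 ms) intervals that overlap are merged.
    """
    if len(trace.times) < 2:
        raise ValueError("blink detection needs at least two gaze samples")
    if callable(crosshair_ref):
        ch = np.asarray(crosshair_ref(trace.times), dtype=float).reshape(-1, 2)
    else:
        ch = np.asarray(crosshair_ref, dtype=float).reshape(-1, 2)
    vx = np.gradient(trace.xy[:, 0], trace.times)
    vy = np.gradient(trace.xy[:, 1], trace.times)
    speed = np.hypot(vx, vy)
    dev = np.linalg.norm(trace.xy - ch, axis=1)
    flagged = (speed > BLINK_SPEED_THRESHOLD) | (dev > BLINK_DEVIATION_THRESHOLD)
    if not flagged.any():
        return []
    raw: list[tuple[float, float]] = []
    idx = np.flatnonzero(flagged)
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            raw.append((trace.times[start], trace.times[prev]))
            start = i
        prev = i
    raw.append((trace.times[start], trace.times[prev]))
    padded = _merge_intervals([(lo - BLINK_PAD, hi + BLINK_PAD) for lo, hi in raw])
    out = []
    for plo, phi in padded:
        # raw sub-intervals covered by this padded span
        members = [(lo, hi) for lo, hi in raw
                   if lo >= plo - 1e-12 and hi <= phi + 1e-12]
        lo = min(m[0] for m in members)
        hi = max(m[1] for m in members)
        out.append(BlinkInterval(start_time=lo, end_time=hi,
                                 padded_start=plo, padded_end=phi,
                                 replacement_source_time=phi + BLINK_PAD))
    return out


def remove_blinks(trial: AlignedTrial,
                  blinks: list[BlinkInterval]) -> AlignedTrial:
    """Replace padded blink spans with a nearby steady gaze position.

    Each padded interval's gaze is overwritten with the constant gaze value
    at 100 ms after its padded end; if that time falls past the trial, the
    value 100 ms before its padded start is used instead.  Idempotent: the
    replacement source lies outside every padded interval, so reapplying
    the same blink list changes nothing.
    """
    if not blinks:
        return trial
    gaze = trial.gaze.copy()
    t0, t1 = trial.times[0], trial.times[-1]
    for b in blinks:
        if b.padded_start <= t0 and b.padded_end >= t1:
            raise TrialUnusableError("blink spans the entire trial")
        src = b.padded_end + BLINK_PAD
        if src > t1:
            src = b.padded_start - BLINK_PAD
            if src < t0:
                raise TrialUnusableError(
                    "no clean gaze sample near the blink to substitute")
        src_idx = int(np.argmin(np.abs(trial.times - src)))
        mask = (trial.times >= b.padded_start) & (trial.times <= b.padded_end)
        gaze[mask] = trial.gaze[src_idx]
    return replace(trial, gaze=gaze)


def drift_correct_trial(trial: AlignedTrial,
                        window: float = DRIFT_WINDOW) -> AlignedTrial:
    """Subtract the mean terminal-Track deviation from the whole trial.

    Computes the mean gaze-minus-crosshair deviation over the last
    ``window`` seconds of the Track phase and subtracts it from the gaze at
    every frame, so slow eye-tracker calibration drift — constant within a
    trial — cancels exactly.  Operating on the deviation rather than raw
    gaze keeps the correction meaningful while the crosshair moves.
    """
    track = trial.phase == "track"
    if not track.any():
        raise TrialUnusableError("trial has no Track frames")
    t_track = trial.times[track]
    if t_track[-1] - t_track[0] < window - 1e-9:
        raise TrialUnusableError(
            f"Track phase shorter than the {window*1e3:.0f} ms drift window")
    in_window = track & (trial.times > t_track[-1] - window + 1e-12)
    dev = trial.gaze - trial.crosshair
    offset = dev[in_window].mean(axis=0)
    return replace(trial, gaze=trial.gaze - offset, drift_corrected=True)


def rmse_per_timepoint(trials: list[AlignedTrial],
                       min_fraction: float = 0.8) -> RmseCurve:
    """RMSE gaze-to-crosshair distance across trials per frame offset.

    Trials are aligned at View onset (time 0; Track appears as negative
    time).  Frame offsets where fewer than ``min_fraction`` of the trials
    contribute are omitted, so the curve is not dominated by the few trials
    with unusually long Track phases.
    """
    if len(trials) < 2:
        raise ValueError("RMSE curve needs at least two trials")
    dt = float(np.median(np.diff(trials[0].times)))
    per_offset: dict[int, list[float]] = {}
    for tr in trials:
        offs = np.round(tr.time_from_view_onset / dt).astype(int)
        dev = tr.deviation
        for k, d in zip(offs, dev):
            per_offset.setdefault(int(k), []).append(float(d))
    min_count = int(math.ceil(min_fraction * len(trials)))
    ks = sorted(k for k, v in per_offset.items() if len(v) >= min_count)
    time = np.array([k * dt for k in ks])
    rmse = np.array([math.sqrt(np.mean(np.square(per_offset[k]))) for k in ks])
    n = np.array([len(per_offset[k]) for k in ks])
    return RmseCurve(time=time, rmse=rmse, n=n)


def relative_rmse(condition: RmseCurve, reference: RmseCurve) -> RmseCurve:
    """Pointwise ratio of a condition's RMSE curve to a reference curve.

    Restricted to the common time support; frames where the reference is
    zero are excluded with a warning.
    """
    dt = float(np.median(np.diff(reference.time))) if len(reference.time) > 1 else 1.0
    ref_idx = {int(round(t / dt)): i for i, t in enumerate(reference.time)}
    times, ratios, ns = [], [], []
    dropped = 0
    for i, t in enumerate(condition.time):
        k = int(round(t / dt))
        if k not in ref_idx:
            continue
        denom = reference.rmse[ref_idx[k]]
        if denom == 0.0:
            dropped += 1
            continue
        times.append(t)
        ratios.append(condition.rmse[i] / denom)
        ns.append(min(condition.n[i], reference.n[ref_idx[k]]))
    if dropped:
        warnings.warn(f"excluded {dropped} frame(s) with zero reference RMSE")
    return RmseCurve(time=np.asarray(times), rmse=np.asarray(ratios),
                     n=np.asarray(ns, dtype=int))


def _trial_breaks(trial: AlignedTrial, tolerance: float,
                  include_track: bool) -> bool:
    mask = trial.phase == "view"
    if include_track:
        mask |= trial.phase == "track"
    if not mask.any():
        raise ValueError("trial has no View frames")
    return bool(np.any(trial.deviation[mask] > tolerance))


def count_breaks(trials: list[AlignedTrial], tolerance: float,
                 include_track: bool = False) -> tuple[int, float]:
    """Trials whose View-interval deviation ever exceeds the tolerance.

    Returns (count, percent of trials).  ``include_track`` extends the scan
    to Track frames for sensitivity analyses.
    """
    count = sum(_trial_breaks(tr, tolerance, include_track) for tr in trials)
    return count, 100.0 * count / len(trials)


def sweep_breaks(trials: list[AlignedTrial], tolerances,
                 include_track: bool = False) -> BreakSweep:
    """Fixation-break percentage at each tolerance (monotone non-increasing)."""
    tolerances = np.asarray(tolerances, dtype=float)
    counts, percents = [], []
    for tol in tolerances:
        c, p = count_breaks(trials, float(tol), include_track)
        counts.append(c)
        percents.append(p)
    return BreakSweep(tolerances=tolerances,
                      break_percent=np.asarray(percents),
                      break_count=np.asarray(counts, dtype=int),
                      n_trials=len(trials))


def cursor_error(trials: list[AlignedTrial]) -> float:
    """RMS cursor-to-crosshair distance over Track frames, pooled, deg."""
    sq = []
    for tr in trials:
        mask = (tr.phase == "track") & ~np.isnan(tr.cursor[:, 0])
        d = np.linalg.norm(tr.cursor[mask] - tr.crosshair[mask], axis=1)
        sq.append(d**2)
    pooled = np.concatenate(sq)
    return float(np.sqrt(pooled.mean()))


def classify_abnormal_bouma(b: float,
                            cutoff: float = ABNORMAL_BOUMA_CUTOFF) -> bool:
    """True iff a Bouma factor is implausibly small (strictly below cutoff).

    The cutoff 0.096 is the smallest Bouma factor observed at 10 deg
    eccentricity in a large gaze-contingent dataset; smaller measured
    values indicate peeking rather than genuinely weak crowding.
    """
    if b <= 0:
        raise ValueError("Bouma factor must be positive")
    return b < cutoff


def summarize_group(values, rng: np.random.Generator | None = None, *,
                    n_boot: int = 10_000,
                    ci_level: float = 0.68) -> tuple[float, float, float]:
    """Geometric mean with a bootstrap confidence interval.

    Resamples the values (sessions) with replacement ``n_boot`` times and
    reports the percentile interval (16th/84th for the default 68% level).
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    if rng is None:
        rng = np.random.default_rng(0)
    logv = np.log(v)
    est = float(np.exp(logv.mean()))
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    boot = np.exp(logv[idx].mean(axis=1))
    lo, hi = np.percentile(boot, [50 * (1 - ci_level), 50 * (1 + ci_level)])
    return est, float(lo), float(hi)


def round_percent(p: float) -> int:
    """Half-up rounding to integer percent (so 8.57% reports as 9%)."""
    return int(math.floor(p + 0.5))
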