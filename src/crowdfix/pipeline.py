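"""Session-level orchestration: logs in, cleaned trials and metrics out."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .gaze import (AlignedTrial, TrialUnusableError, align_gaze_to_frames,
                   cursor_error, detect_blinks,
                   drift_correct_trial, relative_rmse, remove_blinks,
                   rmse_per_timepoint, sweep_breaks, classify_abnormal_bouma)
from .logs import gaze_trace_from_df, split_trials
from .quest import (QuestParams, bouma_from_threshold, init_quest,
                    quest_quantile, quest_update)
from .gaze import GazeTrace

__all__ = [
    "preprocess_trial",
    "preprocess_session",
    "thresholds_from_responses",
    "analyze_session",
    "DEFAULT_TOLERANCES",
]

DEFAULT_TOLERANCES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def preprocess_trial(trial_df: pd.DataFrame, gaze: GazeTrace,
                     drift_correct: bool = True) -> AlignedTrial:
    """Align, de-blink and drift-correct one trial from raw logs.

    Blink detection runs on the native-rate gaze segment overlapping the
    trial, with the crosshair reference interpolated from the frame log
    onto the gaze timestamps.  Raises :class:`TrialUnusableError` when the
    trial cannot be cleaned.
    """
    ft = trial_df["posixTimeSec"].to_numpy()
    phases = trial_df["phase"].to_numpy()
    ch = trial_df[["crosshairXDeg", "crosshairYDeg"]].to_numpy()
    cur = trial_df[["cursorXDeg", "cursorYDeg"]].to_numpy()
    view = trial_df["phase"].to_numpy() == "view"
    if not view.any():
        raise TrialUnusableError("trial has no View frames (skipped trial?)")
    view_onset = float(ft[view][0])

    seg = (gaze.times >= ft[0] - 0.05) & (gaze.times <= ft[-1] + 0.05)
    if seg.sum() < 2:
        raise TrialUnusableError("no gaze coverage for this trial")
    seg_trace = GazeTrace(times=gaze.times[seg], xy=gaze.xy[seg],
                          valid=gaze.valid[seg])

    def crosshair_ref(ts):
        return np.column_stack([np.interp(ts, ft, ch[:, 0]),
                                np.interp(ts, ft, ch[:, 1])])

    blinks = detect_blinks(seg_trace, crosshair_ref)
    aligned = align_gaze_to_frames(ft, phases, ch, cur, seg_trace, view_onset)
    aligned = remove_blinks(aligned, blinks)
    if drift_correct:
        aligned = drift_correct_trial(aligned)
    return aligned


def preprocess_session(frame_df: pd.DataFrame, gaze_df: pd.DataFrame,
                       drift_correct: bool = True):
    """Clean every usable trial; returns {mode: [AlignedTrial]} plus exclusions."""
    gaze = gaze_trace_from_df(gaze_df)
    by_mode: dict[str, list[AlignedTrial]] = {}
    excluded: list[tuple[int, str]] = []
    for idx, tdf in split_trials(frame_df).items():
        mode = str(tdf["fixationMode"].iloc[0])
        try:
            aligned = preprocess_trial(tdf, gaze, drift_correct=drift_correct)
        except TrialUnusableError as err:
            excluded.append((idx, str(err)))
            continue
        by_mode.setdefault(mode, []).append(aligned)
    return by_mode, excluded


def thresholds_from_responses(resp_df: pd.DataFrame,
                              qparams: QuestParams | None = None,
                              eccentricity: float = 10.0) -> pd.DataFrame:
    """Re-run QUEST offline over a response log to recover thresholds.

    Replays each (mode, side) staircase's (spacing, outcome) history through
    a fresh posterior and reports the 53rd-quantile threshold spacing and
    its Bouma factor, flagged when implausibly small.
    """
    qparams = qparams or QuestParams()
    rows = []
    done = resp_df[resp_df["skipped"].astype(int) == 0]
    for (mode, side), grp in done.groupby(["fixationMode", "targetSide"]):
        state = init_quest(qparams)
        for _, r in grp.iterrows():
            state = quest_update(state, math.log10(float(r["spacingDeg"])),
                                 bool(int(r["correct"])), qparams)
        thr = 10.0 ** quest_quantile(state, qparams.threshold_quantile)
        b = bouma_from_threshold(thr, eccentricity)
        rows.append({"fixationMode": mode, "targetSide": side,
                     "nTrials": len(grp), "thresholdSpacingDeg": thr,
                     "boumaFactor": b,
                     "abnormallySmall": int(classify_abnormal_bouma(b))})
    return pd.DataFrame(rows)


def analyze_session(frame_df: pd.DataFrame, gaze_df: pd.DataFrame,
                    resp_df: pd.DataFrame | None = None,
                    tolerances=DEFAULT_TOLERANCES,
                    eccentricity: float = 10.0) -> dict:
    """Full analysis of one session's logs.

    Returns a dict with per-mode RMSE curves, RMSE relative to stationary
    fixation, fixation-break sweeps, RMS cursor tracking error, per-trial
    exclusions, and — when a response log is given — recovered thresholds
    and Bouma screening.
    """
    by_mode, excluded = preprocess_session(frame_df, gaze_df)
    curves = {m: rmse_per_timepoint(trs) for m, trs in by_mode.items()
              if len(trs) >= 2}
    relative = {}
    if "stationary" in curves:
        for m, c in curves.items():
            if m != "stationary":
                relative[m] = relative_rmse(c, curves["stationary"])
    sweeps = {m: sweep_breaks(trs, tolerances) for m, trs in by_mode.items()}
    cursor = {m: cursor_error(trs) for m, trs in by_mode.items()}
    out = {"trials": by_mode, "excluded": excluded, "rmse": curves,
           "relative_rmse": relative, "break_sweep": sweeps,
           "cursor_error": cursor}
    if resp_df is not None:
        out["thresholds"] = thresholds_from_responses(
            resp_df, eccentricity=eccentricity)
    return out
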