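"""CSV dialects: frame log, gaze log, response log, condition table.

Both experiment and eye-tracker exports are plain UTF-8 CSV with POSIX
timestamps in seconds.  Files written by this package start with a single
comment line ``# crowdfix v<version> seed=<seed>`` recording provenance;
readers skip any leading ``#`` lines, key columns by header name (order
free), and report malformed rows with their line numbers.

All positions are in degrees of visual angle.  An optional
``pixelsPerDegree`` key in the condition table enables pixel export for
interoperability with other tools; everything internal stays in degrees.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gaze import GazeTrace

__all__ = [
    "FRAME_LOG_COLUMNS",
    "GAZE_LOG_COLUMNS",
    "RESPONSE_LOG_COLUMNS",
    "FrameLogError",
    "frames_dataframe",
    "responses_dataframe",
    "write_frame_log",
    "read_frame_log",
    "write_gaze_log",
    "read_gaze_log",
    "write_response_log",
    "read_response_log",
    "split_trials",
    "gaze_trace_from_df",
    "write_condition_table",
    "read_condition_table",
    "default_conditions",
]

MAX_DISTRACTORS = 3

FRAME_LOG_COLUMNS = [
    "posixTimeSec", "trialIndex", "phase", "fixationMode",
    "crosshairXDeg", "crosshairYDeg", "cursorXDeg", "cursorYDeg",
    "onCrosshair", "stimulusPresent",
    "distractor1XDeg", "distractor1YDeg", "distractor2XDeg", "distractor2YDeg",
    "distractor3XDeg", "distractor3YDeg", "targetSide", "spacingDeg",
]
GAZE_LOG_COLUMNS = ["posixTimeSec", "gazeXDeg", "gazeYDeg", "valid"]
RESPONSE_LOG_COLUMNS = [
    "trialIndex", "fixationMode", "targetSide", "spacingDeg", "targetLetter",
    "responseLetter", "correct", "skipped", "requiredTrackS",
]


class FrameLogError(ValueError):
    """Malformed or inconsistent log file; message names the offending line."""


def _provenance(seed) -> str:
    return f"# crowdfix v{__version__} seed={seed}\n"


def frames_dataframe(trials, modes: dict[int, str] | None = None) -> pd.DataFrame:
    """Flatten TrialRecords into the frame-log dialect."""
    rows = []
    for tr in trials:
        mode = modes[tr.trial_index] if modes else tr.fixation_mode.value
        for f in tr.frames:
            row = {
                "posixTimeSec": f.posix_time,
                "trialIndex": tr.trial_index,
                "phase": f.phase,
                "fixationMode": mode,
                "crosshairXDeg": f.crosshair_xy[0],
                "crosshairYDeg": f.crosshair_xy[1],
                "cursorXDeg": f.cursor_xy[0] if f.cursor_xy is not None else np.nan,
                "cursorYDeg": f.cursor_xy[1] if f.cursor_xy is not None else np.nan,
                "onCrosshair": int(f.on_crosshair),
                "stimulusPresent": int(f.stimulus_present),
                "targetSide": tr.side,
                "spacingDeg": tr.spacing,
            }
            for k in range(MAX_DISTRACTORS):
                if f.distractor_xy is not None and k < len(f.distractor_xy):
                    row[f"distractor{k+1}XDeg"] = f.distractor_xy[k][0]
                    row[f"distractor{k+1}YDeg"] = f.distractor_xy[k][1]
                else:
                    row[f"distractor{k+1}XDeg"] = np.nan
                    row[f"distractor{k+1}YDeg"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=FRAME_LOG_COLUMNS)


def responses_dataframe(trials) -> pd.DataFrame:
    rows = []
    for tr in trials:
        rows.append({
            "trialIndex": tr.trial_index,
            "fixationMode": tr.fixation_mode.value,
            "targetSide": tr.side,
            "spacingDeg": tr.spacing,
            "targetLetter": tr.trigram.target if tr.trigram else "",
            "responseLetter": tr.response_letter or "",
            "correct": int(bool(tr.correct)) if not tr.skipped else "",
            "skipped": int(tr.skipped),
            "requiredTrackS": tr.required_track_s,
        })
    return pd.DataFrame(rows, columns=RESPONSE_LOG_COLUMNS)


def _write_csv(df: pd.DataFrame, path, seed) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance(seed))
        # 17 significant digits: lossless text round trip for float64
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def _read_csv(path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    n_comment = 0
    for ln in lines:
        if ln.startswith("#"):
            n_comment += 1
        else:
            break
    body = "\n".join(lines[n_comment:])
    header = lines[n_comment].split(",") if len(lines) > n_comment else []
    n_cols = len(header)
    for i, ln in enumerate(lines[n_comment + 1:], start=n_comment + 2):
        if ln and ln.count(",") + 1 != n_cols:
            raise FrameLogError(
                f"{label} {path.name}: malformed row at line {i} "
                f"({ln.count(',') + 1} fields, expected {n_cols})")
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FrameLogError(f"{label} {path.name}: missing columns {missing}")
    return df


def write_frame_log(frame_df: pd.DataFrame, path, seed="none") -> None:
    _write_csv(frame_df[FRAME_LOG_COLUMNS], path, seed)


def read_frame_log(path) -> pd.DataFrame:
    df = _read_csv(path, FRAME_LOG_COLUMNS, "frame log")
    for trial_index, grp in df.groupby("trialIndex"):
        t = grp["posixTimeSec"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            line = int(grp.index[bad + 1]) + 3  # + header + provenance + 1-based
            raise FrameLogError(
                f"frame log: non-monotone time in trial {trial_index} "
                f"near line {line}")
    return df


def write_gaze_log(gaze_df: pd.DataFrame, path, seed="none") -> None:
    _write_csv(gaze_df[GAZE_LOG_COLUMNS], path, seed)


def read_gaze_log(path) -> pd.DataFrame:
    return _read_csv(path, GAZE_LOG_COLUMNS, "gaze log")


def write_response_log(resp_df: pd.DataFrame, path, seed="none") -> None:
    _write_csv(resp_df[RESPONSE_LOG_COLUMNS], path, seed)


def read_response_log(path) -> pd.DataFrame:
    return _read_csv(path, RESPONSE_LOG_COLUMNS, "response log")


def split_trials(frame_df: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Frame log split into per-trial DataFrames, keyed by trial index."""
    return {int(k): g.reset_index(drop=True)
            for k, g in frame_df.groupby("trialIndex", sort=True)}


def gaze_trace_from_df(gaze_df: pd.DataFrame) -> GazeTrace:
    return GazeTrace(times=gaze_df["posixTimeSec"].to_numpy(),
                     xy=gaze_df[["gazeXDeg", "gazeYDeg"]].to_numpy(),
                     valid=gaze_df["valid"].to_numpy().astype(bool))


# --- condition table (one column per condition) ---

def default_conditions() -> pd.DataFrame:
    """The three-condition design: one column per fixation task."""
    params = {
        "fixationMode": ["stationary", "dynamic", "crowded_dynamic"],
        "nTrials": [70, 70, 70],
        "trialsPerSide": [35, 35, 35],
        "eccentricityDeg": [10.0, 10.0, 10.0],
        "viewDurationS": [0.150, 0.150, 0.150],
        "hotspotRadiusDeg": [0.15, 0.15, 0.15],
        "orbitRadiusDeg": [0.5, 0.5, 0.5],
        "orbitSpeedDegPerS": [0.4, 0.4, 0.4],
        "nDistractors": [0, 0, 3],
        "distractorSpeedDegPerS": [1.1, 1.1, 1.1],
        "confinementRadiusDeg": [1.0, 1.0, 1.0],
        "repulsionGain": [0.25, 0.25, 0.25],
        "frameRateHz": [60, 60, 60],
        "gazeRateHz": [100, 100, 100],
    }
    df = pd.DataFrame(params, index=["stationary", "dynamic", "crowded_dynamic"]).T
    df.index.name = "parameter"
    return df


def write_condition_table(df: pd.DataFrame, path, seed="none") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance(seed))
        df.to_csv(fh, lineterminator="\n")


def read_condition_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#", index_col=0)
    required = {"fixationMode", "nTrials", "trialsPerSide", "eccentricityDeg",
                "viewDurationS", "hotspotRadiusDeg"}
    missing = required - set(df.index)
    if missing:
        raise FrameLogError(f"condition table {path.name}: missing parameters "
                            f"{sorted(missing)}")
    return df
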