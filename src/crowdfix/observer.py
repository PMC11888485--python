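"""Synthetic observer: a generative stand-in for a human participant.

Produces the three behavioral streams a real session yields — cursor
positions tracking the crosshair, gaze positions from an eye tracker, and
9AFC letter responses — from a fully specified generative model, so the
whole stimulus / trial / analysis pipeline can be exercised and verified
end to end, including parameter recovery of the observer's true Bouma
factors.

The model:

* **Cursor** — the crosshair position a few frames ago plus isotropic
  Gaussian noise (hand-tracking lag and jitter).
* **Gaze** — smooth pursuit of the crosshair (gain ~1) plus Gaussian noise
  and a slow calibration-drift random walk across trials.  With probability
  ``p_peek`` a trial contains an anticipatory saccade ("peek"): an
  instantaneous horizontal step of random sign — uncorrelated with the
  target side — active from its onset near View onset until the end of
  View.  In the Respond phase gaze saccades to the true target location
  (a harmless response saccade).  Blinks appear as large off-screen
  excursions that trip both blink-detection criteria.
* **Responses** — correct with the Weibull probability of the adaptive
  staircase's psychometric model at the observer's true threshold
  ``log10(bouma_true * eccentricity)``; errors are uniform over the other
  eight letters.  If the trial peeked toward the target side, the effective
  eccentricity drops by the peek amplitude, which is what makes peeking
  produce implausibly low measured thresholds.

Saccades are instantaneous position steps; every metric in scope depends
only on position thresholds, so main-sequence dynamics are not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import deque

import numpy as np
import pandas as pd

from .quest import QuestParams, p_correct
from .stimulus import SLOAN_LETTERS, FixationMode, TrigramSpec
from .trial import BlockConfig, BlockResult, run_block

__all__ = [
    "ObserverParams",
    "PeekEvent",
    "SimSessionTruth",
    "SyntheticObserver",
    "SessionConfig",
    "simulate_cursor_frame",
    "simulate_gaze_frame",
    "simulate_response",
    "generate_session",
    "POSIX_EPOCH_START",
]

#: Arbitrary session start time so logs look like real POSIX exports.
POSIX_EPOCH_START = 1_700_000_000.0


@dataclass(frozen=True)
class ObserverParams:
    """Generative truth for the synthetic participant.

    Bouma factors are per-side (the right visual field tends to be better,
    i.e. smaller).  Noise magnitudes, lag, drift, and blink statistics are
    fixtures chosen to be realistic for a cooperative adult with a mouse
    and a research eye tracker; they are not fitted to any dataset.
    """

    bouma_true_left: float = 0.30
    bouma_true_right: float = 0.25
    psychometric_beta: float = 2.3
    lapse_delta: float = 0.01
    guess_gamma: float = 1.0 / 9.0
    cursor_noise_sd: float = 0.03      # deg per axis
    cursor_lag: int = 2                # frames
    pursuit_gain: float = 1.0
    gaze_noise_sd: float = 0.10        # deg per axis
    calibration_drift_sd: float = 0.05  # deg random-walk step per trial
    p_peek: float = 0.0
    peek_amplitude_mean: float = 3.0   # deg
    peek_amplitude_sd: float = 1.0
    peek_onset_mean: float = -0.05     # s relative to View onset
    peek_onset_sd: float = 0.05
    blink_rate_per_min: float = 2.0
    blink_duration: float = 0.30       # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_peek <= 1.0:
            raise ValueError("p_peek must be a probability")
        for name in ("cursor_noise_sd", "gaze_noise_sd", "calibration_drift_sd",
                     "peek_amplitude_sd", "peek_onset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not math.isclose(self.guess_gamma, 1.0 / len(SLOAN_LETTERS)):
            raise ValueError("guess_gamma must be 1 / alphabet size")

    def bouma_true(self, side: str) -> float:
        return self.bouma_true_left if side == "left" else self.bouma_true_right

    def psychometric(self) -> QuestParams:
        return QuestParams(beta=self.psychometric_beta, delta=self.lapse_delta,
                           gamma=self.guess_gamma)


@dataclass(frozen=True)
class PeekEvent:
    amplitude: float   # deg, horizontal
    sign: float        # +1 rightward, -1 leftward (uncorrelated with target)
    onset: float       # s relative to View onset


@dataclass
class SimSessionTruth:
    """Per-trial ground truth of the generative model, for recovery tests."""

    seed: int
    params: ObserverParams
    trials: pd.DataFrame          # trialIndex, mode, side, peeked, peek fields
    blink_intervals: list[tuple[float, float]]  # POSIX (start, end)
    drift_by_trial: dict[int, np.ndarray]


def simulate_cursor_frame(crosshair_xy, params: ObserverParams,
                          rng: np.random.Generator,
                          lag_buffer: deque | None = None) -> np.ndarray:
    """One cursor sample: lagged crosshair position plus Gaussian jitter.

    ``lag_buffer`` holds recent crosshair positions; when omitted (or lag
    is 0) the current position is used.
    """
    crosshair_xy = np.asarray(crosshair_xy, dtype=float)
    if lag_buffer is not None and params.cursor_lag > 0:
        lag_buffer.append(crosshair_xy.copy())
        target = lag_buffer[0]
    else:
        target = crosshair_xy
    return target + rng.normal(0.0, params.cursor_noise_sd, size=2)


def simulate_gaze_frame(crosshair_xy, phase: str, params: ObserverParams,
                        rng: np.random.Generator, *,
                        drift=(0.0, 0.0), peek_active: bool = False,
                        peek: PeekEvent | None = None,
                        target_xy=None, blinking: bool = False) -> np.ndarray:
    """One gaze sample given the trial phase and active events."""
    crosshair_xy = np.asarray(crosshair_xy, dtype=float)
    if blinking:
        # off-screen excursion: > 20 deg from fixation, reached instantly
        return crosshair_xy + np.array([0.0, -30.0])
    if phase == "respond" and target_xy is not None:
        base = np.asarray(target_xy, dtype=float)
    else:
        base = params.pursuit_gain * crosshair_xy
        if peek_active and peek is not None:
            base = base + np.array([peek.sign * peek.amplitude, 0.0])
    return base + np.asarray(drift, float) + rng.normal(0.0, params.gaze_noise_sd, size=2)


def simulate_response(trigram: TrigramSpec, side: str, params: ObserverParams,
                      rng: np.random.Generator,
                      peek: PeekEvent | None = None) -> str:
    """Draw a 9AFC letter response from the Weibull psychometric model.

    A peek whose random sign lands on the target's side shrinks the
    effective eccentricity by the peek amplitude (floored at 1 deg),
    lowering the effective threshold — the mechanism by which peeking
    yields implausibly low measured thresholds.
    """
    ecc = trigram.eccentricity
    if peek is not None:
        target_sign = 1.0 if side == "right" else -1.0
        if peek.sign == target_sign:
            ecc = max(1.0, ecc - peek.amplitude)
    T = math.log10(params.bouma_true(side) * ecc)
    p = float(p_correct(math.log10(trigram.spacing), T, params.psychometric()))
    if rng.uniform() < p:
        return trigram.target
    others = [c for c in SLOAN_LETTERS if c != trigram.target]
    return str(rng.choice(others))


class SyntheticObserver:
    """Trial agent wiring the generative model into the trial engine."""

    def __init__(self, params: ObserverParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.drift = np.zeros(2)
        self._lag_buffer: deque = deque(maxlen=max(1, params.cursor_lag + 1))
        self.current_peek: PeekEvent | None = None
        self.peek_log: list[dict] = []

    # --- TrialAgent protocol ---

    def start_trial(self, trial_index: int, mode: FixationMode, side: str,
                    spacing: float, rng: np.random.Generator) -> None:
        p = self.params
        self.drift = self.drift + rng.normal(0.0, p.calibration_drift_sd, size=2)
        self._lag_buffer.clear()
        if rng.uniform() < p.p_peek:
            amp = max(0.5, rng.normal(p.peek_amplitude_mean, p.peek_amplitude_sd))
            # onset clipped to 50 ms after View onset so the peek always
            # overlaps the 150-ms stimulus window
            onset = min(rng.normal(p.peek_onset_mean, p.peek_onset_sd), 0.05)
            self.current_peek = PeekEvent(
                amplitude=amp,
                sign=1.0 if rng.uniform() < 0.5 else -1.0,
                onset=onset)
        else:
            self.current_peek = None
        self.peek_log.append({
            "trialIndex": trial_index, "mode": mode.value, "side": side,
            "spacingDeg": spacing, "peeked": self.current_peek is not None,
            "peekAmplitudeDeg": (self.current_peek.amplitude
                                 if self.current_peek else np.nan),
            "peekSign": (self.current_peek.sign if self.current_peek else np.nan),
            "peekOnsetS": (self.current_peek.onset
                           if self.current_peek else np.nan),
            "driftXDeg": self.drift[0], "driftYDeg": self.drift[1],
        })

    def cursor(self, t: float, crosshair_xy: np.ndarray) -> np.ndarray:
        return simulate_cursor_frame(crosshair_xy, self.params, self.rng,
                                     self._lag_buffer)

    def respond(self, trigram: TrigramSpec, side: str) -> str:
        return simulate_response(trigram, side, self.params, self.rng,
                                 peek=self.current_peek)


@dataclass(frozen=True)
class SessionConfig:
    """One experimental session: one block per fixation mode."""

    modes: tuple[FixationMode, ...] = (FixationMode.STATIONARY,
                                       FixationMode.DYNAMIC,
                                       FixationMode.CROWDED_DYNAMIC)
    n_trials: int = 70
    trials_per_side: int = 35
    gaze_rate: float = 100.0   # Hz
    frame_rate: float = 60.0
    interblock_gap: float = 5.0  # s


def _gaze_for_trials(blocks: list[BlockResult], observer: SyntheticObserver,
                     truth_rows: list[dict], cfg: SessionConfig,
                     rng: np.random.Generator):
    """Generate the 100-Hz gaze stream over every logged trial."""
    p = observer.params
    drift_by_trial = {row["trialIndex"]: np.array([row["driftXDeg"],
                                                   row["driftYDeg"]])
                      for row in truth_rows}
    peek_by_trial = {row["trialIndex"]: row for row in truth_rows}
    times, gx, gy = [], [], []
    blink_truth: list[tuple[float, float]] = []
    gdt = 1.0 / cfg.gaze_rate
    for block in blocks:
        for trial in block.all_trials:
            ft = np.array([f.posix_time for f in trial.frames])
            chx = np.array([f.crosshair_xy[0] for f in trial.frames])
            chy = np.array([f.crosshair_xy[1] for f in trial.frames])
            phases = np.array([f.phase for f in trial.frames], dtype=object)
            row = peek_by_trial.get(trial.trial_index, None)
            drift = drift_by_trial.get(trial.trial_index, np.zeros(2))
            peek = None
            if row is not None and row["peeked"]:
                peek = PeekEvent(row["peekAmplitudeDeg"], row["peekSign"],
                                 row["peekOnsetS"])
            # blink schedule: Poisson over the trial duration
            span = ft[-1] - ft[0]
            n_blinks = rng.poisson(p.blink_rate_per_min * span / 60.0)
            blinks = []
            for _ in range(n_blinks):
                b0 = rng.uniform(ft[0] + 0.3, max(ft[0] + 0.31, ft[-1] - 0.6))
                blinks.append((b0, b0 + p.blink_duration))
            # overlapping draws are physically a single longer blink
            blinks.sort()
            merged: list[tuple[float, float]] = []
            for b0, b1 in blinks:
                if merged and b0 <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], b1))
                else:
                    merged.append((b0, b1))
            blinks = merged
            blink_truth.extend(blinks)
            target_xy = (trial.trigram.letter_centers[1]
                         if trial.trigram is not None else None)
            ts = np.arange(ft[0], ft[-1] + 1e-9, gdt)
            cx = np.interp(ts, ft, chx)
            cy = np.interp(ts, ft, chy)
            # map each gaze time to the covering frame's phase
            fidx = np.clip(np.searchsorted(ft, ts, side="right") - 1, 0, len(ft) - 1)
            for t, x, y, fi in zip(ts, cx, cy, fidx):
                phase = phases[fi]
                blinking = any(b0 <= t <= b1 for b0, b1 in blinks)
                peek_active = False
                if peek is not None and trial.view_onset_time is not None:
                    view_end = (trial.view_onset_time
                                + block.config.trial.view_duration)
                    peek_active = (trial.view_onset_time + peek.onset
                                   <= t <= view_end)
                g = simulate_gaze_frame(
                    np.array([x, y]), phase, p, rng, drift=drift,
                    peek_active=peek_active, peek=peek, target_xy=target_xy,
                    blinking=blinking)
                times.append(t)
                gx.append(g[0])
                gy.append(g[1])
    order = np.argsort(times)
    return (np.asarray(times)[order], np.asarray(gx)[order],
            np.asarray(gy)[order], blink_truth)


def generate_session(params: ObserverParams, cfg: SessionConfig, seed: int):
    """Simulate a full session and return its logs and generative truth.

    Runs one 70-trial block per fixation mode through the trial engine with
    QUEST staircases driven by the synthetic observer, then synthesizes the
    eye-tracker stream at ``cfg.gaze_rate`` over the session.  Returns
    ``(frame_df, gaze_df, truth, blocks)`` where the two DataFrames follow
    the frame-log and gaze-log CSV dialects and ``truth`` records every
    latent event.  Byte-identical for identical seeds.
    """
    from .logs import frames_dataframe  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    observer = SyntheticObserver(params, rng)
    blocks: list[BlockResult] = []
    t_clock = POSIX_EPOCH_START
    trial_index = 0
    for mode in cfg.modes:
        bcfg = BlockConfig(fixation_mode=mode, n_trials=cfg.n_trials,
                           trials_per_side=cfg.trials_per_side)
        block = run_block(observer, bcfg, rng, start_time=t_clock,
                          start_index=trial_index)
        blocks.append(block)
        last = block.all_trials[-1].end_time
        t_clock = last + cfg.interblock_gap
        trial_index += len(block.all_trials)

    frame_df = frames_dataframe(
        [tr for b in blocks for tr in b.all_trials],
        modes={tr.trial_index: tr.fixation_mode.value
               for b in blocks for tr in b.all_trials})
    times, gx, gy, blink_truth = _gaze_for_trials(
        blocks, observer, observer.peek_log, cfg, rng)
    gaze_df = pd.DataFrame({
        "posixTimeSec": times, "gazeXDeg": gx, "gazeYDeg": gy,
        "valid": np.ones(len(times), dtype=int)})
    truth = SimSessionTruth(
        seed=seed, params=params, trials=pd.DataFrame(observer.peek_log),
        blink_intervals=blink_truth,
        drift_by_trial={row["trialIndex"]: np.array([row["driftXDeg"],
                                                     row["driftYDeg"]])
                        for row in observer.peek_log})
    return frame_df, gaze_df, truth, blocks
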