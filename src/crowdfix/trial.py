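"""Track / View / Respond trial state machine and 70-trial blocks.

A trial begins in the Track phase: the participant keeps the cursor tip
within the 0.15-deg hotspot of the (possibly moving) crosshair.  Once the
cursor stays on the crosshair continuously for a required duration drawn
uniformly from 0.75-1.25 s, the View phase presents a letter trigram for
150 ms at +/-10 deg eccentricity with the crosshair frozen, cursor and
distractors hidden.  In the Respond phase the participant identifies the
middle letter.  Whenever tracking breaks, the continuous-run accumulator
resets and a fresh required duration is drawn; a trial that spends 30 s in
the Track phase without completing a run is skipped.

A block is 70 trials: two randomly interleaved 35-trial QUEST staircases,
one for the left and one for the right meridian, run at a constant fixation
mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .quest import (QuestParams, QuestState, init_quest, quest_next_intensity,
                    quest_quantile, quest_update)
from .stimulus import (DistractorParams, FixationMode, KinematicsParams,
                       SceneState, TrigramSpec, advance_scene,
                       crosshair_position, init_distractors, layout_trigram)

__all__ = [
    "TrialConfig",
    "BlockConfig",
    "FrameRecord",
    "TrialRecord",
    "BlockResult",
    "TrialAgent",
    "CursorSourceExhausted",
    "is_on_crosshair",
    "sample_required_duration",
    "run_trial",
    "run_block",
]

PHASE_TRACK = "track"
PHASE_VIEW = "view"
PHASE_RESPOND = "respond"


class CursorSourceExhausted(RuntimeError):
    """Raised when a cursor source stops yielding positions mid-trial."""


@dataclass(frozen=True)
class TrialConfig:
    hotspot_radius: float = 0.15
    required_track_range: tuple[float, float] = (0.75, 1.25)
    view_duration: float = 0.150
    track_timeout: float = 30.0
    frame_rate: float = 60.0
    eccentricity: float = 10.0
    respond_duration: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.required_track_range
        if not 0.0 < lo <= hi:
            raise ValueError("required_track_range must satisfy 0 < low <= high")
        if self.view_duration <= 0 or self.hotspot_radius <= 0:
            raise ValueError("view_duration and hotspot_radius must be positive")
        if self.frame_rate <= 0 or self.track_timeout <= 0:
            raise ValueError("frame_rate and track_timeout must be positive")

    @property
    def frame_duration(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_view_frames(self) -> int:
        return int(round(self.view_duration * self.frame_rate))


@dataclass
class FrameRecord:
    """One 60-Hz frame of the experiment log.

    ``crosshair_xy`` holds the (possibly frozen) crosshair reference even in
    the Respond phase, where the crosshair is no longer displayed; it is the
    fixation reference for gaze analysis.  ``cursor_xy`` and
    ``distractor_xy`` are None when hidden.
    """

    posix_time: float
    phase: str
    crosshair_xy: np.ndarray
    cursor_xy: np.ndarray | None
    distractor_xy: np.ndarray | None
    on_crosshair: bool
    stimulus_present: bool


@dataclass
class TrialRecord:
    trial_index: int
    fixation_mode: FixationMode
    side: str
    spacing: float
    frames: list[FrameRecord]
    trigram: TrigramSpec | None
    response_letter: str | None
    correct: bool | None
    skipped: bool
    required_track_s: float
    view_onset_time: float | None

    @property
    def end_time(self) -> float:
        return self.frames[-1].posix_time


class TrialAgent(Protocol):
    """Anything that can drive a trial: a scripted stub or a synthetic observer."""

    def start_trial(self, trial_index: int, mode: FixationMode, side: str,
                    spacing: float, rng: np.random.Generator) -> None: ...

    def cursor(self, t: float, crosshair_xy: np.ndarray) -> np.ndarray | None: ...

    def respond(self, trigram: TrigramSpec, side: str) -> str: ...


def sample_required_duration(cfg: TrialConfig,
                             rng: np.random.Generator) -> float:
    """Draw the required continuous-tracking duration, uniform in 0.75-1.25 s.

    This is the sampler the trial state machine uses both at trial start
    and after every tracking break.
    """
    return float(rng.uniform(*cfg.required_track_range))


def is_on_crosshair(cursor_xy, crosshair_xy, hotspot_radius: float) -> bool:
    """True iff the cursor tip is within the hotspot (boundary inclusive)."""
    d = np.linalg.norm(np.asarray(cursor_xy, float) - np.asarray(crosshair_xy, float))
    return bool(d <= hotspot_radius)


def run_trial(agent: TrialAgent, spacing: float, side: str, mode: FixationMode,
              cfg: TrialConfig, rng: np.random.Generator, *,
              kin: KinematicsParams | None = None,
              dparams: DistractorParams | None = None,
              start_time: float = 0.0, trial_index: int = 0) -> TrialRecord:
    """Run one Track/View/Respond trial against an agent.

    The crosshair starts at a random phase of its orbit unless ``kin`` is
    supplied.  ``t`` passed to the agent's cursor source is seconds from
    trial start.  Raises :class:`CursorSourceExhausted` if the agent returns
    None for a cursor position mid-trial.
    """
    dt = cfg.frame_duration
    if kin is None:
        kin = KinematicsParams(start_phase=rng.uniform(0.0, 2.0 * math.pi))
    if dparams is None:
        dparams = DistractorParams(frame_duration=dt)
    ch0 = crosshair_position(0.0, mode, kin)
    distr = (init_distractors(ch0, dparams, rng)
             if mode.has_distractors else np.zeros((0, 2)))
    scene = SceneState(0.0, ch0, distr)

    required = sample_required_duration(cfg, rng)
    frames: list[FrameRecord] = []
    run = 0.0
    track_elapsed = 0.0
    was_on = False
    frame_idx = 0
    skipped = False
    eps = 1e-9

    # --- Track ---
    while True:
        t = frame_idx * dt
        cursor = agent.cursor(t, scene.crosshair_xy)
        if cursor is None:
            raise CursorSourceExhausted(
                f"cursor source exhausted at t={t:.3f} s in trial {trial_index}")
        cursor = np.asarray(cursor, dtype=float)
        on = is_on_crosshair(cursor, scene.crosshair_xy, cfg.hotspot_radius)
        frames.append(FrameRecord(
            posix_time=start_time + t, phase=PHASE_TRACK,
            crosshair_xy=scene.crosshair_xy.copy(), cursor_xy=cursor,
            distractor_xy=scene.distractor_xy.copy() if mode.has_distractors else None,
            on_crosshair=on, stimulus_present=False))
        if on:
            run += dt
        else:
            if was_on:
                # tracking broke: reset and draw a fresh required duration
                required = sample_required_duration(cfg, rng)
            run = 0.0
        was_on = on
        track_elapsed += dt
        frame_idx += 1
        if run >= required - eps:
            break
        if track_elapsed >= cfg.track_timeout - eps:
            skipped = True
            break
        scene = advance_scene(scene, rng, mode, kin, dparams)

    if skipped:
        return TrialRecord(trial_index, mode, side, spacing, frames,
                           trigram=None, response_letter=None, correct=None,
                           skipped=True, required_track_s=required,
                           view_onset_time=None)

    # --- View: crosshair frozen, cursor and distractors hidden ---
    frozen = scene.crosshair_xy.copy()
    trigram = layout_trigram(frozen, side, spacing, rng,
                             eccentricity=cfg.eccentricity)
    view_onset = start_time + frame_idx * dt
    for _ in range(cfg.n_view_frames):
        frames.append(FrameRecord(
            posix_time=start_time + frame_idx * dt, phase=PHASE_VIEW,
            crosshair_xy=frozen.copy(), cursor_xy=None, distractor_xy=None,
            on_crosshair=False, stimulus_present=True))
        frame_idx += 1

    # --- Respond: crosshair hidden (frozen position kept as reference) ---
    n_respond = int(round(cfg.respond_duration * cfg.frame_rate))
    for _ in range(n_respond):
        frames.append(FrameRecord(
            posix_time=start_time + frame_idx * dt, phase=PHASE_RESPOND,
            crosshair_xy=frozen.copy(), cursor_xy=None, distractor_xy=None,
            on_crosshair=False, stimulus_present=False))
        frame_idx += 1
    response = agent.respond(trigram, side)
    return TrialRecord(trial_index, mode, side, spacing, frames,
                       trigram=trigram, response_letter=response,
                       correct=(response == trigram.target), skipped=False,
                       required_track_s=required, view_onset_time=view_onset)


@dataclass(frozen=True)
class BlockConfig:
    fixation_mode: FixationMode
    n_trials: int = 70
    trials_per_side: int = 35
    trial: TrialConfig = field(default_factory=TrialConfig)
    quest: QuestParams = field(default_factory=QuestParams)
    intertrial_gap: float = 0.5  # s between consecutive trials
    max_attempts_factor: int = 3

    def __post_init__(self) -> None:
        if self.n_trials != 2 * self.trials_per_side:
            raise ValueError("n_trials must equal 2 x trials_per_side")


@dataclass
class BlockResult:
    config: BlockConfig
    trials: list[TrialRecord]
    skipped_trials: list[TrialRecord]
    quest_left: QuestState
    quest_right: QuestState
    threshold_left: float   # deg spacing, 53rd posterior quantile
    threshold_right: float

    @property
    def all_trials(self) -> list[TrialRecord]:
        out = self.trials + self.skipped_trials
        return sorted(out, key=lambda tr: tr.frames[0].posix_time)


def run_block(agent: TrialAgent, cfg: BlockConfig, rng: np.random.Generator, *,
              quest_left: QuestState | None = None,
              quest_right: QuestState | None = None,
              dparams: DistractorParams | None = None,
              start_time: float = 0.0,
              start_index: int = 0) -> BlockResult:
    """Run one block of two randomly interleaved per-side staircases.

    The side sequence is a random permutation of 35 left + 35 right fixed at
    block start, so the per-side split is exact.  Each trial is tested at
    the posterior-mean spacing of its side's staircase and its outcome fed
    back; skipped trials update nothing and their side is re-queued at the
    end of the sequence.
    """
    quests = {
        "left": quest_left if quest_left is not None else init_quest(cfg.quest),
        "right": quest_right if quest_right is not None else init_quest(cfg.quest),
    }
    sides = list(rng.permutation(
        ["left"] * cfg.trials_per_side + ["right"] * cfg.trials_per_side))
    completed: list[TrialRecord] = []
    skipped: list[TrialRecord] = []
    t_clock = start_time
    trial_index = start_index
    attempts = 0
    max_attempts = cfg.max_attempts_factor * cfg.n_trials
    while sides:
        if attempts >= max_attempts:
            raise RuntimeError("block aborted: too many skipped trials")
        side = sides.pop(0)
        intensity = quest_next_intensity(quests[side], cfg.quest)
        spacing = 10.0 ** intensity
        if hasattr(agent, "start_trial"):
            agent.start_trial(trial_index, cfg.fixation_mode, side, spacing, rng)
        trial = run_trial(agent, spacing, side, cfg.fixation_mode, cfg.trial,
                          rng, dparams=dparams, start_time=t_clock,
                          trial_index=trial_index)
        t_clock = trial.end_time + cfg.intertrial_gap
        trial_index += 1
        attempts += 1
        if trial.skipped:
            skipped.append(trial)
            sides.append(side)  # re-queue; QUEST not updated
        else:
            completed.append(trial)
            quests[side] = quest_update(quests[side], math.log10(spacing),
                                        bool(trial.correct), cfg.quest)
    q = cfg.quest.threshold_quantile
    return BlockResult(
        config=cfg, trials=completed, skipped_trials=skipped,
        quest_left=quests["left"], quest_right=quests["right"],
        threshold_left=10.0 ** quest_quantile(quests["left"], q),
        threshold_right=10.0 ** quest_quantile(quests["right"], q),
    )
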