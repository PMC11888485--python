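"""Stimulus kinematics for the crowded dynamic fixation task.

The fixation mark is a crosshair that is either stationary at screen center
or orbits it counterclockwise on a small circle (radius 0.5 deg at a path
speed of 0.4 deg/s by default).  In the crowded variant, three distractor
crosses execute Brownian motion near the fixation crosshair, with a pairwise
inverse-square repulsion that keeps them from clustering and a hard
confinement to within 1 deg of the crosshair.  Peripheral targets are letter
trigrams laid out on the horizontal meridian relative to the crosshair.

All geometry is in degrees of visual angle in a screen-centered,
x-right / y-up coordinate frame.  Conversion to pixels is an I/O concern and
does not appear here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SLOAN_LETTERS",
    "FixationMode",
    "KinematicsParams",
    "DistractorParams",
    "SceneState",
    "TrigramSpec",
    "crosshair_position",
    "brownian_step",
    "repulsion_displacements",
    "advance_scene",
    "init_distractors",
    "layout_trigram",
]

#: Sloan optotype alphabet used for the crowding task; C is excluded because
#: it is too easily confused with O.
SLOAN_LETTERS = "DHKNORSVZ"

#: Ratio of letter size to center-to-center spacing in a trigram.
LETTER_SIZE_TO_SPACING = 0.71


class FixationMode(str, Enum):
    """The three fixation-task variants."""

    STATIONARY = "stationary"
    DYNAMIC = "dynamic"
    CROWDED_DYNAMIC = "crowded_dynamic"

    @property
    def moving(self) -> bool:
        return self is not FixationMode.STATIONARY

    @property
    def has_distractors(self) -> bool:
        return self is FixationMode.CROWDED_DYNAMIC


@dataclass(frozen=True)
class KinematicsParams:
    """Crosshair orbit parameters.

    Parameters
    ----------
    orbit_radius
        Radius of the circular trajectory about screen center, deg.
    orbit_speed
        Path (tangential) speed along the trajectory, deg/s.
    start_phase
        Angular phase at time zero, radians; each trial starts the crosshair
        at a random point on the circle, so this is sampled per trial.
    center
        Center of the trajectory, deg (screen center by convention).
    """

    orbit_radius: float = 0.5
    orbit_speed: float = 0.4
    start_phase: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.orbit_radius <= 0:
            raise ValueError("orbit_radius must be positive")
        if self.orbit_speed <= 0:
            raise ValueError("orbit_speed must be positive")

    @property
    def angular_speed(self) -> float:
        """Counterclockwise angular speed, rad/s."""
        return self.orbit_speed / self.orbit_radius


@dataclass(frozen=True)
class DistractorParams:
    """Distractor motion parameters.

    ``step_speed`` is the instantaneous Brownian speed: every frame each
    distractor takes a step of fixed length ``step_speed * frame_duration``
    in a uniformly random direction.  ``repulsion_gain`` is the constant *g*
    of the inverse-square pairwise repulsion (deg^3/s); the displacement a
    distractor receives from a partner at distance ``d`` has length
    ``g * frame_duration / d**2`` and points away from the partner.
    ``coincidence_floor`` bounds that displacement by capping ``d`` from
    below (one line thickness), so coincident distractors never produce an
    infinite step.
    """

    n_distractors: int = 3
    step_speed: float = 1.1
    confinement_radius: float = 1.0
    repulsion_gain: float = 0.25
    frame_duration: float = 1.0 / 60.0
    distractor_length: float = 0.8  # cosmetic
    distractor_thickness: float = 0.05  # cosmetic
    coincidence_floor: float = 0.05
    min_initial_separation: float = 0.1

    def __post_init__(self) -> None:
        for name in ("confinement_radius", "frame_duration", "distractor_length",
                     "distractor_thickness", "coincidence_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.step_speed < 0 or self.repulsion_gain < 0:
            raise ValueError("step_speed and repulsion_gain must be non-negative")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be non-negative")


@dataclass
class SceneState:
    """Crosshair and distractor positions at one frame time."""

    time: float
    crosshair_xy: np.ndarray
    distractor_xy: np.ndarray  # shape (n, 2); empty for uncrowded modes

    def __post_init__(self) -> None:
        self.crosshair_xy = np.asarray(self.crosshair_xy, dtype=float).reshape(2)
        self.distractor_xy = np.asarray(self.distractor_xy, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class TrigramSpec:
    """Geometry and identity of one three-letter crowding stimulus.

    The middle letter is the target; the outer two are flankers.  Letter
    size is 0.71 times the center-to-center spacing, and the middle letter
    sits at ``eccentricity`` deg horizontally from the crosshair position at
    stimulus onset.
    """

    eccentricity: float
    side: str  # "left" | "right"
    spacing: float
    letter_size: float
    letters: tuple[str, str, str]
    target: str
    letter_centers: np.ndarray = field(repr=False)  # shape (3, 2)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(set(self.letters)) != 3:
            raise ValueError("trigram letters must be pairwise distinct")
        if not math.isclose(self.letter_size, LETTER_SIZE_TO_SPACING * self.spacing):
            raise ValueError("letter_size must equal 0.71 x spacing")


def crosshair_position(time: float, mode: FixationMode,
                       kin: KinematicsParams) -> np.ndarray:
    """Crosshair center at ``time`` seconds after trial start.

    Stationary fixation pins the crosshair at the trajectory center.  In the
    dynamic modes the crosshair moves counterclockwise on a circle of radius
    ``orbit_radius`` at angular speed ``orbit_speed / orbit_radius``.
    """
    if time < 0:
        raise ValueError("time must be non-negative")
    center = np.asarray(kin.center, dtype=float)
    if not mode.moving:
        return center.copy()
    phase = kin.start_phase + kin.angular_speed * time
    return center + kin.orbit_radius * np.array([math.cos(phase), math.sin(phase)])


def brownian_step(rng: np.random.Generator,
                  params: DistractorParams) -> np.ndarray:
    """One fixed-magnitude Brownian step in a uniformly random direction.

    The step length is ``step_speed * frame_duration`` exactly; only the
    direction is random, matching an "instantaneous speed" specification.
    """
    theta = rng.uniform(0.0, 2.0 * math.pi)
    mag = params.step_speed * params.frame_duration
    return mag * np.array([math.cos(theta), math.sin(theta)])


def repulsion_displacements(positions: np.ndarray,
                            params: DistractorParams) -> np.ndarray:
    """Per-distractor displacement from pairwise inverse-square repulsion.

    For each unordered pair (i, j) at distance d, both members receive a
    displacement of length ``g * t / d**2`` along the line joining them,
    directed away from the partner; each distractor's total displacement is
    the vector sum over its pairs.  Distances are capped from below at
    ``coincidence_floor`` so the displacement stays bounded.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("repulsion requires at least two distractors")
    diff = pos[:, None, :] - pos[None, :, :]  # diff[i, j] = pos_i - pos_j
    d = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(d, np.inf)  # no self-interaction
    d_eff = np.maximum(d, params.coincidence_floor)
    h = params.repulsion_gain * params.frame_duration / d_eff**2
    safe = np.where(d == 0.0, 1.0, d)
    unit = diff / safe[..., None]
    coincident = np.argwhere((d == 0.0) & ~np.eye(n, dtype=bool))
    for i, j in coincident:
        # direction undefined; push apart deterministically along +/- x
        unit[i, j] = (1.0, 0.0) if i < j else (-1.0, 0.0)
    return (h[..., None] * unit).sum(axis=1)


def init_distractors(crosshair_xy: np.ndarray, params: DistractorParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Place distractors uniformly in the confinement disk, well separated.

    Resamples the whole configuration until every pair is at least
    ``min_initial_separation`` apart.
    """
    n = params.n_distractors
    crosshair_xy = np.asarray(crosshair_xy, dtype=float)
    if n == 0:
        return np.zeros((0, 2))
    while True:
        r = params.confinement_radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0.0, 2.0 * math.pi, size=n)
        pos = crosshair_xy + np.column_stack([r * np.cos(th), r * np.sin(th)])
        if n < 2:
            return pos
        dists = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= params.min_initial_separation:
            return pos


def advance_scene(state: SceneState, rng: np.random.Generator,
                  mode: FixationMode, kin: KinematicsParams,
                  params: DistractorParams, confine: bool = True) -> SceneState:
    """Advance the scene by one frame.

    Update order within the frame: move the crosshair along its orbit; carry
    the distractors rigidly with the crosshair (their Brownian motion is
    defined in crosshair-relative coordinates); apply each distractor's
    Brownian step; apply pairwise repulsion; finally project any distractor
    that escaped the confinement disk radially back onto its boundary.  The
    order makes the confinement invariant exact after every call.
    """
    dt = params.frame_duration
    new_time = state.time + dt
    new_ch = crosshair_position(new_time, mode, kin)
    pos = state.distractor_xy.copy()
    if pos.shape[0]:
        pos += new_ch - state.crosshair_xy  # rigid advection with crosshair
        for k in range(pos.shape[0]):
            pos[k] += brownian_step(rng, params)
        if pos.shape[0] >= 2:
            pos += repulsion_displacements(pos, params)
        if confine:
            rel = pos - new_ch
            r = np.linalg.norm(rel, axis=1)
            over = r > params.confinement_radius
            if over.any():
                pos[over] = new_ch + rel[over] * (
                    params.confinement_radius / r[over])[:, None]
    return SceneState(new_time, new_ch, pos)


def layout_trigram(crosshair_xy: np.ndarray, side: str, spacing: float,
                   rng: np.random.Generator,
                   eccentricity: float = 10.0) -> TrigramSpec:
    """Lay out a letter trigram on the horizontal meridian.

    Three distinct letters are sampled without replacement from the Sloan
    subset DHKNORSVZ.  The middle letter (the target) is centered
    ``eccentricity`` deg horizontally from ``crosshair_xy`` on the requested
    side; the flankers sit at +/- ``spacing`` deg along the horizontal.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if eccentricity <= 0:
        raise ValueError("eccentricity must be positive")
    crosshair_xy = np.asarray(crosshair_xy, dtype=float)
    sign = 1.0 if side == "right" else -1.0
    middle = crosshair_xy + np.array([sign * eccentricity, 0.0])
    centers = np.array([middle - [spacing, 0.0], middle, middle + [spacing, 0.0]])
    letters = tuple(rng.choice(list(SLOAN_LETTERS), size=3, replace=False))
    return TrigramSpec(
        eccentricity=eccentricity,
        side=side,
        spacing=spacing,
        letter_size=LETTER_SIZE_TO_SPACING * spacing,
        letters=letters,
        target=letters[1],
        letter_centers=centers,
    )
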