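"""QUEST Bayesian adaptive staircase over log10 letter spacing.

Maintains a discrete posterior over the log10 threshold spacing T of a
Weibull psychometric function for a 9-alternative forced-choice letter task,

    p(correct | x, T) = gamma + (1 - gamma - delta) * (1 - exp(-10**(beta*(x - T)))),

where x is the log10 spacing tested, gamma = 1/9 is the guess rate, delta is
the lapse rate and beta the slope.  After each trial the posterior is
updated by Bayes' rule; the next spacing to test is placed at the posterior
mean, and the block's threshold is reported as the 53rd quantile of the
posterior.  Thresholds at a known eccentricity convert to Bouma factors by
the ratio b = spacing / eccentricity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuestParams",
    "QuestState",
    "init_quest",
    "p_correct",
    "quest_update",
    "quest_quantile",
    "quest_next_intensity",
    "bouma_from_threshold",
]


@dataclass(frozen=True)
class QuestParams:
    """Psychometric model and grid/prior configuration.

    The grid covers log10 spacing from 0.1 to 20 deg in steps of 0.005 log
    units; the prior over the log10 threshold is Gaussian with mean
    log10(3 deg) and sd 0.5, wide enough to cover any plausible crowding
    threshold at 10 deg eccentricity.
    """

    grid_min: float = -1.0
    grid_max: float = 1.3
    grid_step: float = 0.005
    prior_mean: float = math.log10(3.0)
    prior_sd: float = 0.5
    beta: float = 2.3
    delta: float = 0.01
    gamma: float = 1.0 / 9.0
    threshold_quantile: float = 0.53
    placement: str = "mean"  # "mean" | "mode"

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must be in [0, 1)")
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.grid_step <= 0 or self.grid_max <= self.grid_min:
            raise ValueError("grid must be non-degenerate")
        if self.placement not in ("mean", "mode"):
            raise ValueError("placement must be 'mean' or 'mode'")

    def make_grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass
class QuestState:
    """Posterior weights over the threshold grid plus the trial history."""

    grid: np.ndarray
    posterior: np.ndarray
    history: list[tuple[float, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.grid.shape != self.posterior.shape:
            raise ValueError("grid and posterior must have matching shapes")


def init_quest(params: QuestParams) -> QuestState:
    """Fresh staircase state with the Gaussian prior on the grid."""
    grid = params.make_grid()
    prior = np.exp(-0.5 * ((grid - params.prior_mean) / params.prior_sd) ** 2)
    return QuestState(grid=grid, posterior=prior / prior.sum())


def p_correct(x, T, params: QuestParams):
    """Weibull probability of a correct response at log10 spacing ``x``.

    Strictly increasing in x, decreasing in T, with range
    (gamma, 1 - delta).  Accepts scalars or arrays (broadcast).
    """
    expo = np.clip(params.beta * (np.asarray(x, dtype=float) - T), -30.0, 30.0)
    return params.gamma + (1.0 - params.gamma - params.delta) * (
        1.0 - np.exp(-np.power(10.0, expo)))


def quest_update(state: QuestState, x: float, outcome: bool,
                 params: QuestParams) -> QuestState:
    """Bayes update of the posterior after one trial at log10 spacing ``x``."""
    p = p_correct(x, state.grid, params)
    likelihood = p if outcome else 1.0 - p
    post = state.posterior * likelihood
    total = post.sum()
    if not total > 0.0:
        raise ValueError("trial outcome has zero likelihood under every "
                         "threshold on the grid")
    return QuestState(grid=state.grid, posterior=post / total,
                      history=state.history + [(float(x), bool(outcome))])


def quest_quantile(state: QuestState, q: float | None = None,
                   params: QuestParams | None = None) -> float:
    """Posterior quantile of the log10 threshold (left-continuous inverse CDF).

    Returns the smallest grid value whose cumulative posterior mass reaches
    ``q``.  With no arguments beyond the state, ``q`` defaults to the
    configured threshold quantile (0.53).
    """
    if q is None:
        q = (params or QuestParams()).threshold_quantile
    cum = np.cumsum(state.posterior)
    cum /= cum[-1]  # guard tiny normalization drift
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(state.grid[min(idx, len(state.grid) - 1)])


def quest_next_intensity(state: QuestState, params: QuestParams) -> float:
    """Recommended log10 spacing for the next trial.

    Posterior mean by default (QUEST-mean placement); posterior mode when
    ``params.placement == "mode"``.  Clamped to the grid range.
    """
    if params.placement == "mode":
        val = float(state.grid[int(np.argmax(state.posterior))])
    else:
        w = state.posterior / state.posterior.sum()
        val = float(np.dot(state.grid, w))
    return min(max(val, float(state.grid[0])), float(state.grid[-1]))


def bouma_from_threshold(spacing_threshold: float, eccentricity: float) -> float:
    """Bouma factor: threshold center-to-center spacing over eccentricity."""
    if spacing_threshold <= 0 or eccentricity <= 0:
        raise ValueError("spacing threshold and eccentricity must be positive")
    return spacing_threshold / eccentricity
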