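import numpy as np
import pytest

from crowdfix import AlignedTrial, FixationMode, TrialConfig, run_trial


class GlueAgent:
    """Scripted agent: cursor glued to the crosshair, always correct."""

    def start_trial(self, *args):
        pass

    def cursor(self, t, crosshair_xy):
        return crosshair_xy

    def respond(self, trigram, side):
        return trigram.target


class AbsentAgent:
    """Scripted agent whose cursor never reaches the hotspot."""

    def start_trial(self, *args):
        pass

    def cursor(self, t, crosshair_xy):
        return crosshair_xy + np.array([5.0, 5.0])

    def respond(self, trigram, side):
        return trigram.target


@pytest.fixture
def glue_agent():
    return GlueAgent()


@pytest.fixture
def absent_agent():
    return AbsentAgent()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_aligned_trial(deviation_by_phase, dt=1.0 / 60.0, t0=1000.0,
                       crosshair_path=None, cursor_offset=None):
    """Build an AlignedTrial with prescribed per-phase gaze deviations.

    ``deviation_by_phase`` is a list of (phase, n_frames, deviation) where
    deviation is a scalar x-offset, an (n, 2) array, or a callable of the
    frame index within the whole trial.
    """
    phases, devs = [], []
    k = 0
    for phase, n, dev in deviation_by_phase:
        for i in range(n):
            phases.append(phase)
            if callable(dev):
                devs.append(np.asarray(dev(k), dtype=float))
            elif np.isscalar(dev):
                devs.append(np.array([dev, 0.0]))
            else:
                devs.append(np.asarray(dev[i], dtype=float))
            k += 1
    n_total = len(phases)
    times = t0 + dt * np.arange(n_total)
    if crosshair_path is None:
        crosshair = np.zeros((n_total, 2))
    else:
        crosshair = np.asarray(crosshair_path, dtype=float)
    gaze = crosshair + np.asarray(devs)
    if cursor_offset is None:
        cursor = crosshair.copy()
    else:
        cursor = crosshair + np.asarray(cursor_offset, dtype=float)
    phases = np.asarray(phases, dtype=object)
    view_idx = np.flatnonzero(phases == "view")
    view_onset = times[view_idx[0]] if len(view_idx) else times[-1]
    return AlignedTrial(times=times, phase=phases, crosshair=crosshair,
                        cursor=cursor, gaze=gaze, valid=np.ones(n_total, bool),
                        view_onset=view_onset)


@pytest.fixture
def trial_factory():
    return make_aligned_trial


@pytest.fixture
def quick_trial(glue_agent):
    """One completed dynamic-fixation trial with a perfect cursor."""
    rng = np.random.default_rng(11)
    return run_trial(glue_agent, 2.0, "right", FixationMode.DYNAMIC,
                     TrialConfig(), rng)
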