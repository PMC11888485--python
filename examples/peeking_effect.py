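"""How peeking corrupts peripheral thresholds — and how breaks reveal it.

Compares a disciplined observer (never peeks) with an undisciplined one
(peeks on every trial): the peeker breaks fixation at moderate tolerances
and their recovered crowding thresholds are biased low, because a saccade
toward the target reduces its effective eccentricity.
"""

from crowdfix import (FixationMode, ObserverParams, SessionConfig,
                      generate_session, sweep_breaks)
from crowdfix.logs import responses_dataframe
from crowdfix.pipeline import preprocess_session, thresholds_from_responses

cfg = SessionConfig(modes=(FixationMode.STATIONARY,), n_trials=70,
                    trials_per_side=35)

for label, p_peek in (("disciplined", 0.0), ("peeker", 1.0)):
    params = ObserverParams(p_peek=p_peek, blink_rate_per_min=0.0)
    breaks, thresholds = [], []
    for seed in (11, 12, 13, 14):
        frame_df, gaze_df, truth, blocks = generate_session(params, cfg, seed)
        by_mode, _ = preprocess_session(frame_df, gaze_df)
        sweep = sweep_breaks(by_mode["stationary"], [1.0, 1.5, 2.0])
        breaks.append(sweep.break_percent[1])
        resp = responses_dataframe([t for b in blocks for t in b.all_trials])
        thresholds.extend(
            thresholds_from_responses(resp)["thresholdSpacingDeg"])
    print(f"{label:12s} breaks at 1.5 deg: "
          f"{sum(breaks) / len(breaks):5.1f}%   "
          f"mean recovered threshold: "
          f"{sum(thresholds) / len(thresholds):.2f} deg")

print("\nBoth observers share the same true threshold (bouma 0.25/0.30 x "
      "10 deg); the peeker's lower recovered value is pure gaze artifact.")
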