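"""Simulate the crowded dynamic fixation stimulus for ten seconds.

Three distractor crosses execute Brownian motion (1.1 deg/s instantaneous
speed) around a crosshair orbiting the screen center at 0.4 deg/s, with
pairwise inverse-square repulsion and hard confinement to 1 deg.
"""

import numpy as np

from crowdfix import (DistractorParams, FixationMode, KinematicsParams,
                      SceneState, advance_scene, crosshair_position,
                      init_distractors, repulsion_displacements)

rng = np.random.default_rng(0)
params = DistractorParams()
kin = KinematicsParams(start_phase=rng.uniform(0, 2 * np.pi))
ch = crosshair_position(0.0, FixationMode.CROWDED_DYNAMIC, kin)
state = SceneState(0.0, ch, init_distractors(ch, params, rng))

dists, pair_min, net = [], [], []
for _ in range(600):  # 10 s at 60 Hz
    state = advance_scene(state, rng, FixationMode.CROWDED_DYNAMIC, kin, params)
    d = np.linalg.norm(state.distractor_xy - state.crosshair_xy, axis=1)
    dists.append(d.max())
    pd = np.linalg.norm(state.distractor_xy[:, None]
                        - state.distractor_xy[None, :], axis=-1)
    np.fill_diagonal(pd, np.inf)
    pair_min.append(pd.min())
    net.append(np.abs(repulsion_displacements(
        state.distractor_xy, params).sum(axis=0)).max())

print(f"max distractor-to-crosshair distance: {max(dists):.3f} deg "
      f"(confinement bound {params.confinement_radius} deg)")
print(f"median closest pair distance:         {np.median(pair_min):.3f} deg "
      f"(repulsion keeps them apart)")
print(f"largest net repulsion per frame:      {max(net):.2e} deg "
      f"(equal-and-opposite pairs cancel)")
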