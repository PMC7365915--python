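"""Simulate a two-state persistent random walk and quantify its persistence.

Builds the two-state fibroblast-like mixture (a fast-persistent minority
state and a slow-erratic majority state), simulates tracks, and prints the
pooled persistence statistic P = <cos(turn angle)>: 1 means straight-line
motion, 0 means directionless diffusion.
"""

import numpy as np

from statewalk import persistence, simulate_track, tracks_to_steps
from statewalk.fixtures import MEF_LIKE_MODEL, ONE_STATE_MODEL

for name, model in [("two-state (MEF-like)", MEF_LIKE_MODEL), ("one-state", ONE_STATE_MODEL)]:
    tracks = [simulate_track(model, 500, rng=np.random.default_rng([42, i])) for i in range(20)]
    steps = tracks_to_steps(tracks)
    p = persistence(steps)
    occ = np.mean(np.concatenate([t.true_states for t in tracks]) == 0)
    print(f"{name:22s}  steps={len(steps):6d}  P={p:.3f}  state-1 occupancy={occ:.3f}")

print()
print("P well above 0 reflects directional memory.  The two-state mixture's")
print("P is close to zero despite both states being persistent in the")
print("polarity frame: its slow state steps rearward (r < 0) about half the")
print("time, and each rearward step flips the observed reference direction,")
print("turning an apparent turn of t into t - pi for the following step.")
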