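"""Detect high-activity foci in a synthetic ratiometric frame.

Builds a disk-shaped cell with three injected bright blobs — one satisfying
all focus criteria, one too small, one too far from the cell edge — and runs
the detector.  A focus must simultaneously be 60% above the mean in-cell
intensity, strictly larger than 100 px, and within 5 px of the cell edge.
"""

from statewalk.fixtures import BlobSpec, FrameSpec, make_foci_frames
from statewalk.foci import detect_foci, foci_by_state, normalize_frame, select_frame_count

spec = FrameSpec(
    noise_sd=0.05,
    blobs=[
        BlobSpec(center=(128, 36), side=12, intensity=4.0),   # qualifies
        BlobSpec(center=(36, 128), side=8, intensity=4.0),    # too small (64 px)
        BlobSpec(center=(128, 128), side=12, intensity=4.0),  # too far from edge
    ],
)
frame, truth = make_foci_frames(spec, seed=0)
result = detect_foci(normalize_frame(frame))

print(f"injected blobs: {len(truth)}; qualifying by construction: "
      f"{sum(t['qualifies'] for t in truth)}; detected: {result.n_foci}")
for f in result.foci:
    print(f"  focus at {tuple(round(c) for c in f.centroid)}, area {f.area} px, "
          f"mean intensity {f.mean_intensity:.2f}")

lengths = [14, 10, 10, 7, 5]
n = select_frame_count(lengths)
print(f"\nframe-count rule: cells with {lengths} frames -> analyze n = {n} "
      f"frames per cell (maximizes n x m over the {sum(l >= n for l in lengths)} "
      "cells that reach it)")

counts = [1, 3, 1, 4, 2]
states = [1, 2, 1, 2, 2]
by_state = foci_by_state(counts, states)
print("\nfoci counts grouped by predicted migration state:")
for s, d in by_state.items():
    print(f"  state {s}: counts {d['counts']}, mean {d['mean']:.2f}")
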