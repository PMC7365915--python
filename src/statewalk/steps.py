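"""Step coordinates, persistence, and histograms for track analysis.

Raw centroid displacements are ambiguous: a large apparent turn can be a real
reorientation or a rearward step of a still-polarized cell.  The model is
therefore compared to the data in step coordinates ``(dx_par, dy_perp)``:
each consecutive triplet of positions is rotated as a rigid body about the
middle point so that the previous displacement points along +x, and the
current displacement's components parallel and perpendicular to it are
recorded.  The signed change of direction ``turn_angle`` (positive for
counter-clockwise turns) comes for free from the same rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import CellTrack

__all__ = [
    "StepSample",
    "StepDataset",
    "Histogram",
    "track_to_steps",
    "persistence",
    "build_histogram",
    "rebin",
]

log = logging.getLogger(__name__)

#: displacements shorter than this (um) leave the rotation undefined
ZERO_STEP_TOL = 1e-9


@dataclass(frozen=True)
class StepSample:
    """One step in rotated coordinates.

    ``step_index`` is the index of the *current* displacement within its
    track (displacement j connects track points j and j+1), so a simulated
    track's ground-truth label for this sample is ``true_states[step_index]``.
    """

    dx_par: float
    dy_perp: float
    turn_angle: float
    cell_id: str
    step_index: int


@dataclass
class StepDataset:
    """Steps pooled over tracks ("amalgamated" before histogramming)."""

    samples: list[StepSample]
    dt: float = 1.0
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def dx_par(self) -> np.ndarray:
        return np.array([s.dx_par for s in self.samples])

    @property
    def dy_perp(self) -> np.ndarray:
        return np.array([s.dy_perp for s in self.samples])

    @property
    def turn_angles(self) -> np.ndarray:
        return np.array([s.turn_angle for s in self.samples])

    def extend(self, other: "StepDataset") -> None:
        if other.dt != self.dt:
            raise ValueError("cannot pool step datasets with different dt")
        self.samples.extend(other.samples)
        self.n_skipped += other.n_skipped


@dataclass
class Histogram:
    """Density-normalized histogram that also retains raw counts."""

    bin_edges: np.ndarray
    densities: np.ndarray
    counts: np.ndarray
    n_total: int = field(default=0)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.densities) + 1:
            raise ValueError("need len(bin_edges) == len(densities) + 1")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.n_total == 0:
            self.n_total = int(self.counts.sum())
        total = float(np.sum(self.densities * np.diff(self.bin_edges)))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"densities must integrate to 1, got {total!r}")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def track_to_steps(track: CellTrack, zero_tol: float = ZERO_STEP_TOL) -> StepDataset:
    """Transform one track into pooled ``(dx_par, dy_perp, turn_angle)`` samples.

    For each triplet ``(p[i-1], p[i], p[i+1])`` the pair of displacements is
    rotated rigidly about ``p[i-1]`` by minus the four-quadrant angle of the
    previous displacement, so the previous step points along +x; the rotated
    current displacement is the sample.  ``dy_perp`` is positive for
    counter-clockwise turns.  A previous displacement shorter than
    ``zero_tol`` makes the rotation undefined: that sample is skipped and
    counted in ``n_skipped``.

    A track of m points yields m - 2 samples (the first step has no
    predecessor).
    """
    if len(track) < 3:
        raise ValueError("need at least 3 track points to form a step sample")

    dx = np.diff(track.xs)
    dy = np.diff(track.ys)
    prev_len = np.hypot(dx[:-1], dy[:-1])
    ang = np.arctan2(dy[:-1], dx[:-1])  # four-quadrant angle of previous step
    c, s = np.cos(ang), np.sin(ang)
    # rotate current displacement by -ang
    dx_par = dx[1:] * c + dy[1:] * s
    dy_perp = -dx[1:] * s + dy[1:] * c
    turn = np.arctan2(dy_perp, dx_par)  # in (-pi, pi]

    samples: list[StepSample] = []
    n_skipped = 0
    for j in range(len(dx_par)):
        if prev_len[j] < zero_tol:
            n_skipped += 1
            continue
        samples.append(
            StepSample(
                dx_par=float(dx_par[j]),
                dy_perp=float(dy_perp[j]),
                turn_angle=float(turn[j]),
                cell_id=track.cell_id,
                step_index=j + 1,
            )
        )
    if n_skipped:
        log.info("track %s: skipped %d zero-length previous steps", track.cell_id, n_skipped)
    return StepDataset(samples=samples, dt=track.sampling_interval(), n_skipped=n_skipped)


def tracks_to_steps(tracks, zero_tol: float = ZERO_STEP_TOL) -> StepDataset:
    """Pool step samples over multiple tracks into one dataset."""
    pooled: StepDataset | None = None
    for track in tracks:
        ds = track_to_steps(track, zero_tol=zero_tol)
        if pooled is None:
            pooled = ds
        else:
            pooled.extend(ds)
    if pooled is None:
        raise ValueError("no tracks given")
    return pooled


def persistence(steps: StepDataset) -> float:
    """Persistence statistic P = <cos(turn_angle)> pooled over all steps.

    1 for straight-line motion, 0 for directionless (diffusive) motion,
    -1 for exact reversals.
    """
    if len(steps) == 0:
        raise ValueError("cannot compute persistence of an empty dataset")
    return float(np.mean(np.cos(steps.turn_angles)))


def rebin(hist: Histogram, target_bins: int) -> Histogram:
    """Merge adjacent bins to roughly ``target_bins`` (counts are summed).

    Used to cheapen objective evaluations during global search; the final
    refinement always runs on the original binning.
    """
    n = len(hist.densities)
    k = max(1, int(np.ceil(n / target_bins)))
    if k == 1:
        return hist
    edge_idx = list(range(0, n, k)) + [n]
    edges = hist.bin_edges[edge_idx]
    counts = np.add.reduceat(hist.counts, edge_idx[:-1])
    densities = counts / (hist.n_total * np.diff(edges))
    return Histogram(bin_edges=edges, densities=densities, counts=counts, n_total=hist.n_total)


def build_histogram(values, bins="fd") -> Histogram:
    """Density-normalized histogram of ``values``.

    ``bins`` follows ``numpy.histogram``: the default Freedman-Diaconis rule
    ("fd"), an integer count, or explicit edges.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("need at least 2 finite values")
    if np.ptp(values) == 0 and (isinstance(bins, str) or np.isscalar(bins)):
        raise ValueError("all values identical: zero range, supply explicit bin edges")
    counts, edges = np.histogram(values, bins=bins)
    n = counts.sum()
    densities = counts / (n * np.diff(edges))
    return Histogram(bin_edges=edges, densities=densities, counts=counts, n_total=int(n))
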