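"""Detection of high-activity foci in ratiometric biosensor images.

A focus is a contiguous region of elevated GTPase activity near the cell
periphery.  Operationally a region qualifies when it simultaneously is
(1) at least ``intensity_excess`` (default 60%) above the mean in-cell
intensity, (2) strictly larger than ``min_area_px`` pixels (default 100),
and (3) has at least one pixel within ``edge_dist_px`` (default 5) of the
cell edge.  The criteria are relative to the cell mean, so detection is
invariant to rescaling the image; the conventional display normalization
(lowest 5% of in-cell pixels = 1) therefore does not change the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import label, regionprops

__all__ = [
    "RatiometricFrame",
    "FociConfig",
    "Focus",
    "FociResult",
    "normalize_frame",
    "detect_foci",
    "select_frame_count",
    "foci_by_state",
]


@dataclass
class RatiometricFrame:
    """One ratiometric activity image with its binary cell mask."""

    intensities: np.ndarray
    mask: np.ndarray
    frame_index: int = 0
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D raster")
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask has no foreground pixels")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class FociConfig:
    """Focus criteria; defaults follow the standard three-rule definition."""

    intensity_excess: float = 0.60
    min_area_px: int = 100
    edge_dist_px: float = 5.0
    connectivity: int = 2  # skimage convention: 1 = 4-connected, 2 = 8-connected

    def __post_init__(self) -> None:
        if self.intensity_excess <= 0 or self.min_area_px <= 0 or self.edge_dist_px <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-neighbors) or 2 (8-neighbors)")


@dataclass(frozen=True)
class Focus:
    """One detected focus: pixel set (row, col), area, centroid, mean intensity."""

    pixels: frozenset
    area: int
    centroid: tuple[float, float]
    mean_intensity: float


@dataclass
class FociResult:
    """Foci of one frame."""

    n_foci: int
    foci: list[Focus] = field(default_factory=list)
    frame_index: int = 0
    cell_id: str = ""


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile with floor rounding: the k-th smallest value,
    k = max(1, floor(pct/100 * N))."""
    v = np.sort(np.asarray(values).ravel())
    k = max(1, int(np.floor(pct / 100.0 * len(v))))
    return float(v[k - 1])


def normalize_frame(frame: RatiometricFrame, pct: float = 5.0) -> RatiometricFrame:
    """Scale in-mask intensities so the lowest ``pct``% of the cell equals 1.

    Divides in-mask pixels by the nearest-rank ``pct``-th percentile of the
    in-mask values; out-of-mask pixels are untouched.  Purely a display
    convention — detection criteria are scale-invariant.
    """
    ref = _nearest_rank_percentile(frame.intensities[frame.mask], pct)
    if ref <= 0:
        raise ValueError(f"the {pct}th percentile of in-mask intensities is not positive")
    out = frame.intensities.copy()
    out[frame.mask] = out[frame.mask] / ref
    return replace(frame, intensities=out)


def _edge_distance(mask: np.ndarray) -> np.ndarray:
    """Distance (px) of each pixel to the cell edge.

    The edge is the set of in-mask pixels with at least one out-of-mask
    4-neighbor (image-border pixels of the mask count as edge); distances
    are Euclidean to the nearest edge pixel.
    """
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[1:-1, 1:-1]
        & padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    edge = mask & ~interior
    if not edge.any():
        return np.zeros_like(mask, dtype=float)
    return distance_transform_edt(~edge)


def detect_foci(frame: RatiometricFrame, cfg: FociConfig = FociConfig()) -> FociResult:
    """Find all regions satisfying the intensity, area and edge criteria.

    Thresholds in-mask pixels at ``(1 + intensity_excess) * mean`` of the
    in-mask intensities, labels connected components, and keeps components
    with area strictly greater than ``min_area_px`` whose minimum distance
    to the cell edge is at most ``edge_dist_px``.
    """
    mean = frame.intensities[frame.mask].mean()
    hot = frame.mask & (frame.intensities > (1.0 + cfg.intensity_excess) * mean)
    labeled = label(hot, connectivity=cfg.connectivity)
    edge_dist = _edge_distance(frame.mask)

    foci: list[Focus] = []
    for region in regionprops(labeled, intensity_image=frame.intensities):
        if region.area <= cfg.min_area_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if edge_dist[rr, cc].min() > cfg.edge_dist_px:
            continue
        foci.append(
            Focus(
                pixels=frozenset(map(tuple, region.coords)),
                area=int(region.area),
                centroid=tuple(map(float, region.centroid)),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return FociResult(
        n_foci=len(foci), foci=foci, frame_index=frame.frame_index, cell_id=frame.cell_id
    )


def select_frame_count(track_lengths) -> int:
    """Number of frames n to analyze per cell, maximizing n * m.

    ``m`` is the number of cells with at least ``n`` frames; this avoids
    over-weighting long-lived cells.  Ties break toward larger ``n``.
    """
    lengths = np.asarray(list(track_lengths), dtype=int)
    if len(lengths) == 0:
        raise ValueError("empty list of frame counts")
    if np.any(lengths <= 0):
        raise ValueError("frame counts must be positive")
    best_n, best_score = 0, -1
    for n in sorted(set(lengths.tolist())):
        score = n * int(np.sum(lengths >= n))
        if score > best_score or (score == best_score and n > best_n):
            best_n, best_score = n, score
    return best_n


def foci_by_state(foci_counts, state_assignments) -> dict:
    """Group per-frame foci counts by predicted migration state.

    Returns ``{state: {"counts": [...], "mean": float, "median": float}}``;
    states with no frames get an empty count list and NaN summaries.
    """
    counts = list(foci_counts)
    states = list(state_assignments)
    if len(counts) != len(states):
        raise ValueError("foci_counts and state_assignments lengths differ")
    out: dict = {}
    for s in sorted(set(states)):
        cs = [c for c, si in zip(counts, states) if si == s]
        out[s] = {
            "counts": cs,
            "mean": float(np.mean(cs)) if cs else float("nan"),
            "median": float(np.median(cs)) if cs else float("nan"),
        }
    return out
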