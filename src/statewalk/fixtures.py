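"""Deterministic synthetic-data generators with known ground truth.

No public cell-track dataset accompanies the migration analyses this
package implements, so these generators stand in for experimental data in
every test and validation experiment.  Two track scenarios are provided:

* ``mef_like`` — a two-state mixture patterned on the fitted wild-type
  fibroblast values: 12% of steps in a fast-persistent state with a
  characteristic ~3 um step and angular dispersion 0.7, the rest in a
  slow, weakly persistent state with angular dispersion 1.3.  The
  step-size dispersions and the slow state's mean step are not constrained
  by published fits; the defaults (sigma_r1 = 1.0, mu_r2 = 0.0,
  sigma_r2 = 2.0) give a clearly bimodal parallel-step distribution.
* ``one_state`` — a single persistent state, the behaviour of wild-type
  HeLa cells.

Synthetic ratiometric frames carry flat-top blobs on a disk-shaped cell
mask, with ground truth recording which blobs satisfy each focus criterion.
All generators are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .foci import FociConfig, RatiometricFrame
from .model import CellTrack, MixtureModel, StateParams, simulate_track

__all__ = [
    "MEF_LIKE_MODEL",
    "ONE_STATE_MODEL",
    "BlobSpec",
    "FrameSpec",
    "make_mef_like",
    "make_one_state",
    "make_tracks",
    "make_foci_frames",
]

#: Two-state fixture; alpha, mu_r1 (~3 um step), sigma_theta1 and sigma_theta2
#: follow the published wild-type fibroblast fit, the remaining dispersions
#: are package defaults (see module docstring).
MEF_LIKE_MODEL = MixtureModel(
    states=(
        StateParams(mu_r=3.0, sigma_r=1.0, sigma_theta=0.7, label="fast-persistent"),
        StateParams(mu_r=0.0, sigma_r=2.0, sigma_theta=1.3, label="slow-erratic"),
    ),
    alphas=(0.12, 0.88),
)

#: Single-state fixture (HeLa-like persistent migration).
ONE_STATE_MODEL = MixtureModel(
    states=(StateParams(mu_r=1.5, sigma_r=1.0, sigma_theta=0.9, label="single"),),
    alphas=(1.0,),
)


def make_tracks(
    model: MixtureModel,
    n_tracks: int,
    n_steps: int,
    seed: int,
    cell_prefix: str = "cell",
) -> list[CellTrack]:
    """Simulate ``n_tracks`` independent tracks of ``n_steps`` steps each.

    Each track gets its own child generator of ``seed``, a random starting
    position in a 500 um field and a random initial polarity angle.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    tracks = []
    for i in range(n_tracks):
        rng = np.random.default_rng([seed, i])
        start = tuple(rng.uniform(0.0, 500.0, size=2))
        angle = rng.uniform(-np.pi, np.pi)
        tracks.append(
            simulate_track(
                model, n_steps, start=start, start_angle=angle, rng=rng,
                cell_id=f"{cell_prefix}{i:03d}",
            )
        )
    return tracks


def make_mef_like(seed: int, n_tracks: int = 50, n_steps: int = 100) -> list[CellTrack]:
    """Two-state fibroblast-like tracks with ground-truth state labels."""
    return make_tracks(MEF_LIKE_MODEL, n_tracks, n_steps, seed, cell_prefix="mef")


def make_one_state(
    params: StateParams | None = None, seed: int = 0, n_tracks: int = 50, n_steps: int = 100
) -> list[CellTrack]:
    """Single-state tracks (HeLa-like); ``params`` overrides the default state."""
    model = ONE_STATE_MODEL if params is None else MixtureModel([params], (1.0,))
    return make_tracks(model, n_tracks, n_steps, seed, cell_prefix="hela")


# ---------------------------------------------------------------------------
# synthetic ratiometric frames


@dataclass(frozen=True)
class BlobSpec:
    """One flat-top blob: center (row, col), side (px), intensity.

    ``area_px`` carves an exact pixel count (row-major within the bounding
    square, always 4-connected), which lets tests sit a blob exactly on an
    area threshold; otherwise the blob is the full ``side x side`` square.
    """

    center: tuple[int, int]
    side: int
    intensity: float
    area_px: int | None = None


@dataclass
class FrameSpec:
    """A disk-mask frame with injected blobs on a uniform background."""

    shape: tuple[int, int] = (256, 256)
    disk_center: tuple[int, int] = (128, 128)
    disk_radius: int = 100
    background: float = 1.0
    noise_sd: float = 0.0
    blobs: list[BlobSpec] = field(default_factory=list)


def _disk_mask(spec: FrameSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    return (rr - spec.disk_center[0]) ** 2 + (cc - spec.disk_center[1]) ** 2 <= spec.disk_radius**2


def make_foci_frames(
    spec: FrameSpec,
    seed: int = 0,
    frame_index: int = 0,
    cell_id: str = "synth",
    cfg: FociConfig = FociConfig(),
) -> tuple[RatiometricFrame, list[dict]]:
    """Build one synthetic frame plus per-blob ground truth.

    Returns the frame and, for each blob, a record of its pixel set and
    whether it satisfies the intensity, area and edge criteria of ``cfg``
    evaluated by brute force against the constructed image.  Blobs must lie
    fully inside the mask.
    """
    from .foci import _edge_distance

    mask = _disk_mask(spec)
    rng = np.random.default_rng(seed)
    img = np.full(spec.shape, spec.background, dtype=float)
    if spec.noise_sd > 0:
        img[mask] += rng.normal(0.0, spec.noise_sd, size=int(mask.sum()))
        img = np.clip(img, 0.0, None)
    img[~mask] = 0.0

    blob_pixels: list[np.ndarray] = []
    for blob in spec.blobs:
        side = blob.side
        if blob.area_px is not None:
            side = int(np.ceil(np.sqrt(blob.area_px)))
        r0 = blob.center[0] - side // 2
        c0 = blob.center[1] - side // 2
        rr, cc = np.mgrid[r0 : r0 + side, c0 : c0 + side]
        px = np.column_stack([rr.ravel(), cc.ravel()])
        if blob.area_px is not None:
            px = px[: blob.area_px]
        inside = (
            (px[:, 0] >= 0) & (px[:, 0] < spec.shape[0])
            & (px[:, 1] >= 0) & (px[:, 1] < spec.shape[1])
        )
        if not np.all(inside) or not np.all(mask[px[:, 0], px[:, 1]]):
            raise ValueError(f"blob at {blob.center} extends outside the cell mask")
        img[px[:, 0], px[:, 1]] = blob.intensity
        blob_pixels.append(px)

    frame = RatiometricFrame(img, mask, frame_index=frame_index, cell_id=cell_id)

    # brute-force ground truth per blob, independent of the detector
    mean = img[mask].mean()
    edge_dist = _edge_distance(mask)
    truth = []
    for blob, px in zip(spec.blobs, blob_pixels):
        truth.append(
            {
                "pixels": frozenset(map(tuple, px)),
                "bright_enough": blob.intensity > (1.0 + cfg.intensity_excess) * mean,
                "big_enough": len(px) > cfg.min_area_px,
                "near_edge": bool(edge_dist[px[:, 0], px[:, 1]].min() <= cfg.edge_dist_px),
            }
        )
        truth[-1]["qualifies"] = (
            truth[-1]["bright_enough"] and truth[-1]["big_enough"] and truth[-1]["near_edge"]
        )
    return frame, truth
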