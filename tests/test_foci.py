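"""Foci detection: normalization, the three criteria, frame-count rule,
state grouping."""

import numpy as np
import pytest

from statewalk.fixtures import BlobSpec, FrameSpec, make_foci_frames
from statewalk.foci import (
    FociConfig,
    RatiometricFrame,
    detect_foci,
    foci_by_state,
    normalize_frame,
    select_frame_count,
)


def _disk_frame(intensity=1.0, shape=(200, 200), radius=80):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (rr - shape[0] // 2) ** 2 + (cc - shape[1] // 2) ** 2 <= radius**2
    img = np.where(mask, intensity, 0.0)
    return RatiometricFrame(img, mask)


class TestNormalize:
    def test_constant_cell_becomes_one(self):
        f = normalize_frame(_disk_frame(intensity=7.3))
        assert np.allclose(f.intensities[f.mask], 1.0)
        assert np.all(f.intensities[~f.mask] == 0.0)

    def test_nearest_rank_fifth_percentile(self):
        # in-mask values 1..100, one pixel each: the 5th percentile under the
        # floor nearest-rank rule is 5, and exactly 5% of pixels end up <= 1
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :] = True
        img = np.arange(1.0, 101.0).reshape(10, 10)
        f = normalize_frame(RatiometricFrame(img, mask))
        assert np.allclose(f.intensities, img / 5.0)
        assert np.sum(f.intensities[f.mask] <= 1.0) == 5

    def test_idempotent_when_reference_is_one(self):
        mask = np.ones((10, 10), dtype=bool)
        img = np.arange(1.0, 101.0).reshape(10, 10)
        once = normalize_frame(RatiometricFrame(img, mask))
        twice = normalize_frame(once)
        assert np.allclose(twice.intensities, once.intensities / 1.0, atol=1e-12)

    def test_nonpositive_reference_rejected(self):
        mask = np.ones((10, 10), dtype=bool)
        img = np.zeros((10, 10))
        img[5:, :] = 3.0
        with pytest.raises(ValueError):
            normalize_frame(RatiometricFrame(img, mask))


class TestDetectFoci:
    def _frame_with_square(self, side, offset_from_edge=0, intensity=2.0):
        """200x200 disk of background 1.0 with one bright square; offset 0
        places the square's outer edge on the cell boundary."""
        f = _disk_frame(intensity=1.0)
        center_r = 100
        # left-most point of the disk is at column 100 - 80 = 20
        c0 = 20 + offset_from_edge
        img = f.intensities.copy()
        img[center_r - side // 2 : center_r - side // 2 + side, c0 : c0 + side] = intensity
        return RatiometricFrame(img, f.mask)

    def test_qualifying_square_is_found_exactly(self):
        frame = self._frame_with_square(side=12)
        res = detect_foci(frame)
        assert res.n_foci == 1
        focus = res.foci[0]
        # the disk boundary clips the square: the focus is exactly the
        # bright in-mask pixel set
        expected = {
            (r, c)
            for r in range(94, 106)
            for c in range(20, 32)
            if frame.mask[r, c]
        }
        assert len(expected) > 100
        assert focus.area == len(expected)
        assert focus.pixels == frozenset(expected)

    def test_small_region_rejected_by_area(self):
        assert detect_foci(self._frame_with_square(side=8)).n_foci == 0

    def test_interior_region_rejected_by_edge_distance(self):
        assert detect_foci(self._frame_with_square(side=12, offset_from_edge=40)).n_foci == 0

    def test_dim_region_rejected_by_intensity(self):
        # mean is ~1, threshold 1.6x mean; 1.5 is 50% above, not 60%
        assert detect_foci(self._frame_with_square(side=12, intensity=1.5)).n_foci == 0

    def test_area_threshold_is_strict(self):
        frame = self._frame_with_square(side=12)
        area = detect_foci(frame).foci[0].area
        assert detect_foci(frame, FociConfig(min_area_px=area)).n_foci == 0
        assert detect_foci(frame, FociConfig(min_area_px=area - 1)).n_foci == 1

    def test_scale_invariance(self, rng):
        f = _disk_frame()
        img = f.intensities.copy()
        img[f.mask] += rng.random(int(f.mask.sum()))
        img[90:110, 20:40] = 5.0
        a = detect_foci(RatiometricFrame(img, f.mask))
        b = detect_foci(RatiometricFrame(img * 37.5, f.mask))
        assert a.n_foci == b.n_foci == 1
        assert a.foci[0].pixels == b.foci[0].pixels

    def test_normalization_does_not_change_detection(self, rng):
        f = _disk_frame()
        img = f.intensities.copy()
        img[f.mask] += 0.2 * rng.random(int(f.mask.sum()))
        img[90:110, 20:40] = 4.0
        raw = RatiometricFrame(img, f.mask)
        assert detect_foci(raw).n_foci == detect_foci(normalize_frame(raw)).n_foci


class TestFrameCount:
    def test_documented_example(self):
        assert select_frame_count([10, 8, 5]) == 8  # 8*2=16 beats 10 and 15

    def test_all_equal_lengths(self):
        assert select_frame_count([7, 7, 7]) == 7

    def test_single_cell(self):
        assert select_frame_count([42]) == 42

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            lengths = rng.integers(1, 60, size=rng.integers(1, 12))
            scores = {n: n * int(np.sum(lengths >= n)) for n in set(lengths.tolist())}
            best = max(scores.values())
            oracle = max(n for n, s in scores.items() if s == best)  # ties -> larger n
            assert select_frame_count(lengths) == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_frame_count([])


class TestFociByState:
    def test_bookkeeping(self):
        out = foci_by_state([1, 3, 1, 4], [1, 2, 1, 2])
        assert out[1]["counts"] == [1, 1] and out[2]["counts"] == [3, 4]
        assert out[2]["mean"] == pytest.approx(3.5)

    def test_single_state_leaves_other_empty(self):
        out = foci_by_state([2, 2], [0, 0])
        assert list(out.keys()) == [0]

    def test_total_count_conserved(self, rng):
        counts = rng.integers(0, 6, size=30).tolist()
        states = rng.integers(1, 3, size=30).tolist()
        out = foci_by_state(counts, states)
        assert sum(sum(v["counts"]) for v in out.values()) == sum(counts)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            foci_by_state([1, 2], [1])

    def test_state_with_more_injected_blobs_has_higher_mean(self):
        """Frames tagged state 2 carry systematically more qualifying blobs;
        the per-state summary must reflect that ordering."""
        counts, states = [], []
        for i in range(12):
            state = 1 if i % 3 == 0 else 2
            n_blobs = 1 if state == 1 else 3
            # blobs sit at radius 90 of the radius-100 disk: every blob has
            # pixels within 5 px of the cell edge, so all three criteria hold
            angles = np.linspace(0, 2 * np.pi, n_blobs, endpoint=False) + 0.3 * i
            blobs = [
                BlobSpec(
                    center=(int(128 + 90 * np.sin(a)), int(128 + 90 * np.cos(a))),
                    side=12,
                    intensity=4.0,
                )
                for a in angles
            ]
            spec = FrameSpec(disk_radius=100, blobs=blobs)
            frame, _ = make_foci_frames(spec, seed=i)
            counts.append(detect_foci(frame).n_foci)
            states.append(state)
        out = foci_by_state(counts, states)
        assert out[2]["mean"] > out[1]["mean"]
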