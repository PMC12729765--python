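"""Annotation removal (threshold + largest component) and window sampling."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceusalnm.preprocess import (
    CropRegion,
    binarize,
    compute_crop,
    crop_frames,
    largest_component_bbox,
    preprocess_clip,
    sample_frames,
)


def flood_fill_bbox(mask):
    """Brute-force BFS labelling oracle (8-connectivity), same tie-break."""
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    best = None  # (-size, y0, x0, bbox)
    for y in range(H):
        for x in range(W):
            if mask[y, x] and not seen[y, x]:
                q = deque([(y, x)])
                seen[y, x] = True
                pix = []
                while q:
                    cy, cx = q.popleft()
                    pix.append((cy, cx))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                q.append((ny, nx))
                ys = [p[0] for p in pix]
                xs = [p[1] for p in pix]
                key = (-len(pix), min(ys), min(xs))
                if best is None or key < best[0]:
                    best = (key, CropRegion(min(xs), min(ys), max(xs) + 1, max(ys) + 1))
    return best[1]


class TestBinarize:
    def test_all_zero(self):
        assert not binarize(np.zeros((8, 8), np.uint8), 50).any()

    def test_strict_inequality_at_threshold(self):
        assert not binarize(np.full((4, 4), 50, np.uint8), 50).any()
        assert binarize(np.full((4, 4), 51, np.uint8), 50).all()

    def test_block_count(self):
        img = np.zeros((32, 32), np.uint8)
        img[5:15, 10:20] = 200
        assert binarize(img, 50).sum() == 100

    def test_errors(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((0, 0), np.uint8))
        with pytest.raises(ValueError):
            binarize(np.zeros((4, 4, 3), np.uint8))


class TestLargestComponentBbox:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 7] = True
        assert largest_component_bbox(mask).as_tuple() == (7, 3, 8, 4)

    def test_larger_component_wins(self):
        mask = np.zeros((20, 20), bool)
        mask[0:10, 0:10] = True
        mask[15:18, 15:18] = True
        assert largest_component_bbox(mask).as_tuple() == (0, 0, 10, 10)

    def test_l_shape_eight_connected(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 1] = True  # vertical bar rows 2-6, col 1
        mask[6, 1:5] = True  # horizontal bar row 6, cols 1-4
        assert largest_component_bbox(mask).as_tuple() == (1, 2, 5, 7)
        assert flood_fill_bbox(mask).as_tuple() == (1, 2, 5, 7)

    def test_diagonal_touch_is_connected(self):
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        assert largest_component_bbox(mask).as_tuple() == (0, 0, 3, 3)

    def test_tie_breaks_topmost_leftmost(self):
        mask = np.zeros((10, 10), bool)
        mask[6:8, 6:8] = True  # later 4-pixel block
        mask[1:3, 1:3] = True  # earlier 4-pixel block
        assert largest_component_bbox(mask).as_tuple() == (1, 1, 3, 3)

    def test_all_false_errors(self):
        with pytest.raises(ValueError, match="no foreground"):
            largest_component_bbox(np.zeros((5, 5), bool))

    def test_oracle_agreement_random_masks(self):
        """Implementation matches brute-force BFS on 50 random 32x32 masks."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            mask = rng.random((32, 32)) < rng.uniform(0.2, 0.6)
            if not mask.any():
                continue
            assert largest_component_bbox(mask).as_tuple() == flood_fill_bbox(mask).as_tuple()


class TestCropFrames:
    def test_identity(self):
        frames = np.arange(2 * 8 * 8, dtype=np.uint8).reshape(2, 8, 8)
        out = crop_frames(frames, CropRegion(0, 0, 8, 8), (8, 8))
        np.testing.assert_array_equal(out, frames)

    def test_output_shape(self):
        frames = np.zeros((3, 128, 128), np.uint8)
        out = crop_frames(frames, CropRegion(16, 16, 112, 112), (64, 64))
        assert out.shape == (3, 64, 64)

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            crop_frames(np.zeros((1, 32, 32)), CropRegion(0, 0, 40, 40))

    def test_crop_excludes_annotation_band(self, noiseless_dataset, noiseless_config):
        """On a noiseless render the threshold-50 crop recovers exactly the
        imaging-region rectangle, excluding the bright top band."""
        expected = noiseless_config.imaging_region()
        for s in noiseless_dataset:
            region = compute_crop(s.frames[s.keyframe_index], 50)
            assert region.as_tuple() == expected
            assert region.y0 >= noiseless_config.band_height

    def test_crop_idempotent(self, noiseless_dataset):
        s = noiseless_dataset[0]
        region = compute_crop(s.frames[s.keyframe_index], 50)
        once = crop_frames(s.frames[s.keyframe_index], region)
        again = compute_crop(once, 50)
        assert again.as_tuple() == (0, 0, region.width, region.height)


class TestSampleFrames:
    def test_pinned_central_window(self):
        assert sample_frames(120, 50) == [45, 46, 47, 48, 49, 50, 51, 52, 53, 55]

    def test_boundary_shift_start(self):
        idx = sample_frames(120, 2)
        assert idx[0] == 0 and idx[-1] == 10
        assert idx == [int(np.floor(p)) for p in np.linspace(0, 10, 10)]

    def test_boundary_shift_end(self):
        idx = sample_frames(120, 118)
        assert idx[0] == 109 and idx[-1] == 119

    def test_n_out_equals_window_length(self):
        assert sample_frames(120, 50, half_window=5, n_out=11) == list(range(45, 56))

    def test_window_too_short_errors(self):
        with pytest.raises(ValueError):
            sample_frames(11, 5, half_window=2, n_out=10)

    def test_keyframe_out_of_range(self):
        with pytest.raises(ValueError):
            sample_frames(100, 100)

    @given(
        n_total=st.integers(11, 300),
        kf_frac=st.floats(0.0, 1.0),
        half_window=st.integers(5, 20),
        n_out=st.integers(2, 11),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_n_out_unique_increasing_in_range(self, n_total, kf_frac, half_window, n_out):
        keyframe = min(int(kf_frac * n_total), n_total - 1)
        if 2 * half_window + 1 < n_out:
            return
        idx = sample_frames(n_total, keyframe, half_window, n_out)
        assert len(idx) == n_out
        assert all(0 <= i < n_total for i in idx)
        assert all(b > a for a, b in zip(idx, idx[1:]))


def test_load_frames_directory_and_tiff(tmp_path, rng):
    import imageio.v3 as iio

    from ceusalnm.preprocess import load_frames

    frames = rng.integers(0, 255, size=(4, 16, 16), dtype=np.uint8)
    d = tmp_path / "clip"
    d.mkdir()
    for t, f in enumerate(frames):
        iio.imwrite(d / f"frame_{t:03d}.png", f)
    np.testing.assert_array_equal(load_frames(d), frames)

    tif = tmp_path / "clip.tif"
    iio.imwrite(tif, frames)
    np.testing.assert_array_equal(load_frames(tif), frames)

    with pytest.raises(ValueError):
        load_frames(tmp_path / "clip.bin")


def test_preprocess_clip_pipeline(noiseless_dataset, noiseless_config):
    s = noiseless_dataset[0]
    clip, indices, region = preprocess_clip(s.frames, s.keyframe_index, out_size=(64, 64))
    assert clip.shape == (10, 64, 64)
    assert clip.min() >= 0.0 and clip.max() <= 1.0
    assert region.as_tuple() == noiseless_config.imaging_region()
    assert len(indices) == 10
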