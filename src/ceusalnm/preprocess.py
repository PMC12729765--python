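"""Frame preprocessing: annotation removal and keyframe-window sampling.

Ultrasound exports carry device text, parameter read-outs and black margins
around the actual imaging region.  The cleanup is deliberately simple and
fully deterministic:

1. binarize the keyframe at a fixed intensity threshold (default 50, strict
   ``>``),
2. take the bounding rectangle of the largest 8-connected foreground
   component as the imaging region,
3. crop every frame of the clip to that rectangle and resize to the model
   input size.

Model input frames are then sampled uniformly from a +/-5-frame window
around the reader-selected keyframe (10 of the 11 window frames by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import resize as sk_resize


@dataclass(frozen=True)
class CropRegion:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty crop region")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


def load_frames(path: str | Path) -> np.ndarray:
    """Read a clip as a (T, H, W) uint8 stack.

    ``path`` may be a directory of numbered PNG/JPEG frames (sorted by
    name) or a single multi-frame TIFF.  Colour frames are converted to
    grayscale by channel averaging.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"no PNG/JPEG frames in {path}")
        frames = np.stack([iio.imread(p) for p in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise ValueError("expected a frame directory or a multi-frame TIFF")
    if frames.ndim == 4:  # (T, H, W, C) -> grayscale
        frames = frames.mean(axis=-1)
    return np.clip(frames, 0, 255).astype(np.uint8)


def binarize(image: np.ndarray, threshold: float = 50) -> np.ndarray:
    """Foreground mask: pixel strictly greater than ``threshold``."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    if image.size == 0:
        raise ValueError("empty image")
    return image > threshold


def largest_component_bbox(mask: np.ndarray) -> CropRegion:
    """Tight bbox of the largest 8-connected component of a binary mask.

    Ties on pixel count are broken by the smallest bbox top-left corner
    (y0 first, then x0).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D mask")
    if not mask.any():
        raise ValueError("no foreground: mask is all false")
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = None
    for lbl in np.flatnonzero(counts == counts.max()):
        ys, xs = np.nonzero(labels == lbl)
        region = CropRegion(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        key = (region.y0, region.x0)
        if best is None or key < best[0]:
            best = (key, region)
    return best[1]


def compute_crop(keyframe_image: np.ndarray, threshold: float = 50) -> CropRegion:
    """Imaging-region rectangle from one keyframe (binarize + largest bbox)."""
    return largest_component_bbox(binarize(keyframe_image, threshold))


def crop_frames(frames: np.ndarray, region: CropRegion,
                out_size: tuple[int, int] | None = None) -> np.ndarray:
    """Crop all frames of a clip to ``region`` and resize to ``out_size`` (H, W).

    The region is computed once (from the keyframe) and applied unchanged to
    every frame, avoiding per-frame crop jitter.  Resize is bilinear; when
    the crop already has the requested size the frames pass through exactly.
    """
    frames = np.asarray(frames)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    T, H, W = frames.shape
    if not (0 <= region.x0 < region.x1 <= W and 0 <= region.y0 < region.y1 <= H):
        raise ValueError("crop region outside frame bounds")
    cropped = frames[:, region.y0 : region.y1, region.x0 : region.x1]
    if out_size is not None and (region.height, region.width) != tuple(out_size):
        dtype = cropped.dtype
        out = sk_resize(
            cropped.astype(np.float64),
            (T, out_size[0], out_size[1]),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        cropped = out.astype(dtype) if np.issubdtype(dtype, np.integer) else out
    return cropped[0] if single else cropped


def sample_frames(n_total: int, keyframe: int, half_window: int = 5,
                  n_out: int = 10) -> list[int]:
    """Uniformly sample ``n_out`` frame indices from the keyframe window.

    The window is [keyframe - half_window, keyframe + half_window], *shifted*
    (never shrunk) when it abuts a clip boundary.  Indices are the floor of
    ``n_out`` evenly spaced real positions spanning the window inclusive,
    which for the default 11-frame window keeps 10 strictly increasing
    frames.
    """
    if not 0 <= keyframe < n_total:
        raise ValueError("keyframe out of range")
    if n_total < n_out:
        raise ValueError("clip shorter than the number of requested frames")
    lo = keyframe - half_window
    hi = keyframe + half_window
    if lo < 0:
        hi -= lo
        lo = 0
    if hi > n_total - 1:
        lo -= hi - (n_total - 1)
        hi = n_total - 1
    lo = max(lo, 0)
    if hi - lo + 1 < n_out:
        raise ValueError("keyframe window shorter than n_out after clamping")
    positions = np.linspace(lo, hi, n_out)
    return [int(np.floor(p)) for p in positions]


def preprocess_clip(frames: np.ndarray, keyframe: int, threshold: float = 50,
                    half_window: int = 5, n_out: int = 10,
                    out_size: tuple[int, int] = (64, 64)) -> tuple[np.ndarray, list[int], CropRegion]:
    """Full pipeline for one clip: crop from the keyframe, sample the window.

    Returns (frames scaled to [0, 1] float64 of shape (n_out, *out_size),
    sampled indices, crop region).
    """
    region = compute_crop(frames[keyframe], threshold)
    indices = sample_frames(frames.shape[0], keyframe, half_window, n_out)
    sampled = crop_frames(frames[indices], region, out_size)
    return sampled.astype(np.float64) / 255.0, indices, region
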