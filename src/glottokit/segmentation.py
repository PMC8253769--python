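"""Per-frame glottis segmentation.

The glottis appears as a dark, lens-shaped opening between the bright
vocal folds.  Two segmenters share one contract (frames in, binary masks
out):

* :func:`segment_threshold` - a classical baseline (intensity inversion,
  Otsu threshold, largest centered connected component) that needs no
  trained weights and is used throughout the test suite;
* :func:`segment_model` - inference through any pluggable model handle
  (e.g. an encoder-decoder network trained on annotated endoscopy frames)
  that maps a single frame to a per-pixel glottis probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import InvalidParameterError, InvalidRoiError

__all__ = [
    "VideoFrames",
    "SegmentationSequence",
    "apply_roi",
    "segment_threshold",
    "segment_model",
]


@dataclass
class VideoFrames:
    """A stack of video frames with acquisition metadata.

    frames : (N, H, W) or (N, H, W, 3) uint8 array
    frame_rate : frames per second
    roi : (x, y, w, h) crop already applied, in original-image pixels
    """

    frames: np.ndarray
    frame_rate: float = 4000.0
    roi: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise InvalidParameterError("frames must be (N, H, W[, 3])")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def to_gray(self) -> np.ndarray:
        """Luma conversion (Rec.601) for color stacks; identity for gray."""
        if self.frames.ndim == 3:
            return self.frames.astype(float)
        w = np.array([0.299, 0.587, 0.114])
        return self.frames.astype(float) @ w


@dataclass
class SegmentationSequence:
    """Binary glottis masks aligned to a frame stack."""

    masks: np.ndarray
    frame_rate: float = 4000.0
    roi: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3:
            raise InvalidParameterError("masks must be (N, H, W)")
        self.masks = (m > 0).astype(np.uint8)
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def areas(self) -> np.ndarray:
        """Segmented pixel count per frame."""
        return self.masks.reshape(self.n_frames, -1).sum(axis=1).astype(float)


def apply_roi(video: VideoFrames, roi: tuple[int, int, int, int]) -> VideoFrames:
    """Crop a frame stack to a rectangular region of interest.

    ``roi`` is ``(x, y, w, h)`` in pixel coordinates (x right, y down,
    0-based).  Idempotent for an identical full-frame roi.
    """
    x, y, w, h = (int(v) for v in roi)
    H, W = video.shape
    if w <= 0 or h <= 0:
        raise InvalidRoiError(f"roi {roi} has zero area")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise InvalidRoiError(f"roi {roi} outside {W}x{H} frame bounds")
    return VideoFrames(
        frames=video.frames[:, y : y + h, x : x + w],
        frame_rate=video.frame_rate,
        roi=(x, y, w, h),
    )


@dataclass
class ThresholdConfig:
    """Knobs of the classical baseline segmenter.

    min_contrast : minimal Otsu class separation (8-bit counts) for a
        frame to contain any dark object at all; below it the mask is
        empty (a fully closed glottis shows only bright tissue).
    center_frac : fraction of the image (centered box) a component must
        overlap to be the glottis candidate.
    darkness_margin : candidate pixels must lie at least this far below
        the frame median (set between the tissue-texture spread and the
        glottis intensity; the glottis is far darker than any tissue).
    """

    min_contrast: float = 20.0
    center_frac: float = 0.5
    darkness_margin: float = 60.0


def _segment_frame(gray: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    inv = gray.max() - gray
    if inv.max() - inv.min() < cfg.min_contrast:
        return np.zeros(gray.shape, dtype=np.uint8)
    thr = threshold_otsu(inv)
    fg = inv > thr
    # Otsu always splits; demand real separation between the classes
    if fg.all() or not fg.any() or (inv[fg].mean() - inv[~fg].mean()) < cfg.min_contrast:
        return np.zeros(gray.shape, dtype=np.uint8)
    labels = measure.label(fg, connectivity=2)
    H, W = gray.shape
    cy, cx = H // 2, W // 2
    hy, hx = int(H * cfg.center_frac / 2), int(W * cfg.center_frac / 2)
    center = np.zeros_like(fg)
    center[cy - hy : cy + hy + 1, cx - hx : cx + hx + 1] = True
    best_label, best_overlap = 0, 0
    for region in measure.regionprops(labels):
        overlap = int(np.count_nonzero(center[tuple(region.coords.T)]))
        if overlap > best_overlap:
            best_label, best_overlap = region.label, overlap
    if best_label == 0:
        return np.zeros(gray.shape, dtype=np.uint8)
    mask = labels == best_label
    # trim attached dark-texture pixels: the glottis is far darker than
    # any tissue, so keep only pixels well below the frame median
    mask &= gray <= np.median(gray) - cfg.darkness_margin
    if not mask.any() or gray[mask].mean() > np.median(gray) - cfg.darkness_margin:
        return np.zeros(gray.shape, dtype=np.uint8)
    labels2 = measure.label(mask, connectivity=2)
    counts = np.bincount(labels2.ravel())
    counts[0] = 0
    return (labels2 == counts.argmax()).astype(np.uint8)


def segment_threshold(
    video: VideoFrames, config: ThresholdConfig | None = None
) -> SegmentationSequence:
    """Classical glottis segmentation baseline.

    Per frame: invert intensity, Otsu-threshold, label connected
    components and keep the one with the largest overlap with the frame
    center region, provided it is genuinely darker than the surrounding
    tissue.  Degenerate frames (uniform, bright, closed glottis) yield an
    empty mask rather than an error.
    """
    if video.n_frames == 0:
        raise InvalidParameterError("video is empty")
    cfg = config or ThresholdConfig()
    gray = video.to_gray()
    masks = np.stack([_segment_frame(g, cfg) for g in gray])
    return SegmentationSequence(masks, video.frame_rate, video.roi)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest connected component of a binary mask."""
    labels = measure.label(mask > 0, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=np.uint8)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


def segment_model(
    video: VideoFrames,
    model: Callable[[np.ndarray], np.ndarray],
    batch_size: int = 16,
    threshold: float = 0.5,
    keep_largest: bool = True,
) -> SegmentationSequence:
    """Run a pluggable segmentation model over every frame.

    ``model`` maps one frame (H, W[, 3]) to a per-pixel glottis
    probability map of shape (H, W); maps are binarized at ``threshold``
    and optionally post-filtered to the largest connected component.
    ``batch_size`` only chunks the Python loop (models see single frames).
    """
    if video.n_frames == 0:
        raise InvalidParameterError("video is empty")
    H, W = video.shape
    masks = np.empty((video.n_frames, H, W), dtype=np.uint8)
    for i in range(video.n_frames):
        prob = np.asarray(model(video.frames[i]), dtype=float)
        if prob.shape != (H, W):
            raise InvalidParameterError(
                f"model returned shape {prob.shape}, expected {(H, W)}"
            )
        m = (prob > threshold).astype(np.uint8)
        masks[i] = largest_component(m) if keep_largest else m
    return SegmentationSequence(masks, video.frame_rate, video.roi)
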