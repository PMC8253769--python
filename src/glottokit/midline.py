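"""Glottal midline estimation, commissure points and hemi-GAWs.

The glottal midline is the anterior-posterior symmetry axis of the
glottis.  It is estimated at each cycle maximum from the segmentation
mask (summed with a few neighboring frames for temporal context) as the
principal axis through the mask centroid, either via image moments or
PCA of the pixel coordinates.  Intersecting the midline with the mask
extent yields the posterior and anterior glottis points; classifying
every mask pixel by the side of the midline it falls on splits the GAW
into left and right vocal-fold contributions (hemi-GAWs).

Coordinates are 0-based image coordinates, x right, y down.  By default
the image-top extreme is taken as the posterior commissure (typical 70
degree rigid-endoscope orientation); "left"/"right" are image-left and
image-right, the anatomical mapping is deliberately not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidParameterError, MidlineUndefinedError
from .segmentation import SegmentationSequence
from .waveform import CycleSet

__all__ = [
    "MidlineEstimate",
    "HemiGAW",
    "estimate_midline",
    "anterior_posterior_points",
    "split_hemi_gaw",
]


@dataclass
class MidlineEstimate:
    """Symmetry axis at one anchor frame.

    centroid : (x, y) of the supporting (summed) mask
    direction : unit vector along the midline, pointing posterior->anterior
    posterior_point / anterior_point : midline intersections with the mask
        extent, (x, y); filled by :func:`anterior_posterior_points`
    degenerate : True when the mask had no preferred axis and the
        orientation is arbitrary
    """

    anchor_frame: int
    centroid: np.ndarray
    direction: np.ndarray
    posterior_point: np.ndarray | None = None
    anterior_point: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise InvalidParameterError("direction must be nonzero")
        self.direction = d / n

    @property
    def normal(self) -> np.ndarray:
        """Unit perpendicular; positive side = image-right of the midline."""
        dx, dy = self.direction
        return np.array([dy, -dx])

    def to_dict(self) -> dict:
        return {
            "anchor_frame": int(self.anchor_frame),
            "centroid": self.centroid.tolist(),
            "direction": self.direction.tolist(),
            "posterior_point": None
            if self.posterior_point is None
            else np.asarray(self.posterior_point).tolist(),
            "anterior_point": None
            if self.anterior_point is None
            else np.asarray(self.anterior_point).tolist(),
            "degenerate": bool(self.degenerate),
        }


@dataclass
class HemiGAW:
    """Per-frame glottal area split by the midline."""

    left_area: np.ndarray
    right_area: np.ndarray
    frame_rate: float = 4000.0

    def __post_init__(self) -> None:
        self.left_area = np.asarray(self.left_area, dtype=float)
        self.right_area = np.asarray(self.right_area, dtype=float)
        if self.left_area.shape != self.right_area.shape:
            raise InvalidParameterError("hemi-GAW arrays must match in length")

    @property
    def total(self) -> np.ndarray:
        return self.left_area + self.right_area


def _mask_coords(mask: np.ndarray, weights: np.ndarray | None = None):
    ys, xs = np.nonzero(mask)
    w = np.ones(xs.size) if weights is None else weights[ys, xs].astype(float)
    return xs.astype(float), ys.astype(float), w


def _principal_axis(
    summed: np.ndarray, method: Literal["moments", "pca"], degeneracy_tol: float = 0.95
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Centroid + dominant-axis unit vector of a weighted mask."""
    xs, ys, w = _mask_coords(summed > 0, summed)
    if xs.size == 0:
        raise MidlineUndefinedError("empty summed mask")
    wsum = w.sum()
    cx, cy = (w * xs).sum() / wsum, (w * ys).sum() / wsum
    dx, dy = xs - cx, ys - cy
    mu20 = (w * dx * dx).sum() / wsum
    mu02 = (w * dy * dy).sum() / wsum
    mu11 = (w * dx * dy).sum() / wsum
    if method == "moments":
        theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
        direction = np.array([np.cos(theta), np.sin(theta)])
    elif method == "pca":
        cov = np.array([[mu20, mu11], [mu11, mu02]])
        evals, evecs = np.linalg.eigh(cov)
        direction = evecs[:, np.argmax(evals)]
    else:
        raise InvalidParameterError(f"unknown midline method {method!r}")
    # eigenvalues of the coordinate covariance quantify elongation
    tr, det = mu20 + mu02, mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4 - det, 0.0)
    lam_hi = tr / 2 + np.sqrt(disc)
    lam_lo = tr / 2 - np.sqrt(disc)
    degenerate = lam_hi <= 0 or (lam_lo / lam_hi) > degeneracy_tol
    return np.array([cx, cy]), direction, degenerate


def _orient(direction: np.ndarray, posterior_at_top: bool) -> np.ndarray:
    """Point the axis posterior->anterior for the configured orientation."""
    d = direction.copy()
    want_positive_y = posterior_at_top  # anterior at image bottom (larger y)
    if d[1] == 0:
        return d if d[0] > 0 else -d
    if (d[1] > 0) != want_positive_y:
        d = -d
    return d


def estimate_midline(
    seg: SegmentationSequence,
    cycles: CycleSet,
    method: Literal["moments", "pca"] = "moments",
    context_frames: int = 2,
    posterior_at_top: bool = True,
    with_endpoints: bool = True,
) -> list[MidlineEstimate]:
    """Estimate the midline at every cycle maximum.

    Masks in ``[max_i - context_frames, max_i + context_frames]`` are
    summed (temporal context stabilizes the axis against per-frame
    segmentation noise); the midline is the line through the summed-mask
    centroid along its principal axis.  Cycles whose summed mask is empty
    raise :class:`MidlineUndefinedError`; a mask with no preferred axis
    (near-circular) is returned with ``degenerate=True``.
    """
    if cycles.n_cycles < 1:
        raise InvalidParameterError("need at least one cycle")
    estimates = []
    for i in range(cycles.n_cycles):
        m = int(cycles.max_idx[i])
        lo = max(m - context_frames, 0)
        hi = min(m + context_frames + 1, seg.n_frames)
        summed = seg.masks[lo:hi].sum(axis=0)
        centroid, direction, degenerate = _principal_axis(summed, method)
        est = MidlineEstimate(
            anchor_frame=m,
            centroid=centroid,
            direction=_orient(direction, posterior_at_top),
            degenerate=degenerate,
        )
        if with_endpoints:
            post, ant = anterior_posterior_points(est, summed > 0)
            est.posterior_point, est.anterior_point = post, ant
        estimates.append(est)
    return estimates


def anterior_posterior_points(
    midline: MidlineEstimate, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior and anterior glottis points.

    Mask pixels are projected onto the midline direction; the extreme
    projections, dropped back onto the midline, give the two commissure
    points.  With the default orientation convention the minimal
    projection (image-top for a posterior-at-top setup) is posterior.
    """
    xs, ys, _ = _mask_coords(np.asarray(mask) > 0)
    if xs.size == 0:
        raise MidlineUndefinedError("empty mask")
    rel = np.stack([xs, ys], axis=1) - midline.centroid
    t = rel @ midline.direction
    posterior = midline.centroid + t.min() * midline.direction
    anterior = midline.centroid + t.max() * midline.direction
    return posterior, anterior


def _nearest_anchor(midlines: list[MidlineEstimate], frame: int) -> MidlineEstimate:
    anchors = np.array([m.anchor_frame for m in midlines])
    return midlines[int(np.argmin(np.abs(anchors - frame)))]


def split_hemi_gaw(
    seg: SegmentationSequence, midlines: list[MidlineEstimate]
) -> HemiGAW:
    """Split every frame's glottal area into left/right of the midline.

    Each mask pixel is assigned by the sign of its signed perpendicular
    distance to the temporally nearest anchor midline; pixels within half
    a pixel of the line contribute half to each side, so left + right
    equals the total GAW exactly for every frame.
    """
    if not midlines:
        raise InvalidParameterError("no midline estimates available")
    n = seg.n_frames
    left = np.zeros(n)
    right = np.zeros(n)
    H, W = seg.masks.shape[1:]
    yy, xx = np.mgrid[0:H, 0:W]
    for f in range(n):
        mask = seg.masks[f] > 0
        if not mask.any():
            continue
        ml = _nearest_anchor(midlines, f)
        sx = xx[mask] - ml.centroid[0]
        sy = yy[mask] - ml.centroid[1]
        s = sx * ml.normal[0] + sy * ml.normal[1]
        on_line = np.abs(s) < 0.5
        right[f] = np.count_nonzero(s >= 0.5) + 0.5 * np.count_nonzero(on_line)
        left[f] = np.count_nonzero(s <= -0.5) + 0.5 * np.count_nonzero(on_line)
    return HemiGAW(left, right, seg.frame_rate)
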