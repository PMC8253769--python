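"""Phonovibrogram (PVG) computation.

The PVG unrolls the vibrating vocal-fold edges into a single 2-D image:
for every frame (columns) and every station along the glottal midline
between posterior and anterior commissure (rows), it stores the lateral
distance from the midline to the farthest glottis pixel on that side.
Left-fold distances fill the top half with the posterior-most station in
row 0; right-fold distances mirror below so the anterior ends of both
folds meet at the horizontal center line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, MidlineUndefinedError
from .midline import MidlineEstimate, _nearest_anchor
from .segmentation import SegmentationSequence

__all__ = ["Phonovibrogram", "compute_pvg"]


@dataclass
class Phonovibrogram:
    """2M x T matrix of lateral displacements (pixels, >= 0).

    Rows 0..M-1: left fold, posterior -> anterior; rows M..2M-1: right
    fold, anterior -> posterior (mirrored).  Columns are frames.
    """

    matrix: np.ndarray
    frame_rate: float
    station_spacing_px: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] % 2:
            raise InvalidParameterError("PVG must be 2-D with an even row count")
        if np.any(self.matrix < 0):
            raise InvalidParameterError("PVG values must be non-negative")

    @property
    def n_stations(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def metadata(self) -> dict:
        return {
            "layout": "rows 0..M-1 left fold posterior->anterior; "
            "rows M..2M-1 right fold anterior->posterior",
            "n_stations": self.n_stations,
            "frame_rate": self.frame_rate,
            "station_spacing_px": self.station_spacing_px,
            "normalization": "none (raw pixel distances)",
        }


def compute_pvg(
    seg: SegmentationSequence,
    midlines: list[MidlineEstimate],
    M: int = 64,
) -> Phonovibrogram:
    """Compute the phonovibrogram from masks and midline estimates.

    For each frame, mask pixels are projected onto the temporally nearest
    anchor midline; the posterior->anterior span is divided into ``M``
    equidistant stations and each station row receives the maximal
    perpendicular distance of the pixels falling within +-0.5 station
    spacing of it, separately for each side of the midline.  Frames with
    empty masks yield all-zero columns.
    """
    if M < 2:
        raise InvalidParameterError("M must be >= 2")
    if not midlines:
        raise MidlineUndefinedError("no midline estimates available")
    for ml in midlines:
        if ml.posterior_point is None or ml.anterior_point is None:
            raise MidlineUndefinedError(
                "midline estimates need anterior/posterior points for the PVG"
            )
    T = seg.n_frames
    out = np.zeros((2 * M, T))
    H, W = seg.masks.shape[1:]
    yy, xx = np.mgrid[0:H, 0:W]
    lengths = []
    for f in range(T):
        mask = seg.masks[f] > 0
        if not mask.any():
            continue
        ml = _nearest_anchor(midlines, f)
        post = np.asarray(ml.posterior_point, dtype=float)
        ant = np.asarray(ml.anterior_point, dtype=float)
        axis = ant - post
        length = float(np.linalg.norm(axis))
        if length == 0:
            continue
        lengths.append(length)
        u = axis / length
        px = xx[mask] - post[0]
        py = yy[mask] - post[1]
        frac = (px * u[0] + py * u[1]) / length
        s = px * ml.normal[0] + py * ml.normal[1]
        inside = (frac >= 0) & (frac <= 1)
        if not inside.any():
            continue
        station = np.clip((frac[inside] * M).astype(int), 0, M - 1)
        si = s[inside]
        left_sel = si < 0
        col = np.zeros(2 * M)
        np.maximum.at(col[:M], station[left_sel], -si[left_sel])
        right = np.zeros(M)
        np.maximum.at(right, station[~left_sel], si[~left_sel])
        col[M:] = right[::-1]  # mirror: anterior ends meet at the center
        out[:, f] = col
    spacing = float(np.mean(lengths) / M) if lengths else float("nan")
    return Phonovibrogram(out, seg.frame_rate, spacing)
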