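"""Glottal area waveform (GAW), cycle detection and phase decomposition.

The GAW is the per-frame count of segmented glottis pixels over time --
the primary one-dimensional vibration signal.  Cycles are delimited
minimum-to-minimum around detected area maxima; each cycle is then split
into an opening phase (closure -> maximum), a closing phase (maximum ->
closure) and a closed phase (area at or below the closure threshold).
These phase durations are the substrate of all quotient parameters
(OQ, CQ, SQ, AQ, RQ, SI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, TooFewCyclesError
from .segmentation import SegmentationSequence

__all__ = ["GAW", "CycleSet", "gaw_from_masks", "detect_cycles", "decompose_phases"]


@dataclass
class GAW:
    """Glottal area versus time.

    area : per-frame glottal area (pixels or arbitrary units), >= 0
    frame_rate : video frame rate in fps; time axis is index / fps
    """

    area: np.ndarray
    frame_rate: float = 4000.0

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if self.area.ndim != 1:
            raise InvalidParameterError("GAW area must be 1-D")
        if np.any(self.area < 0):
            raise InvalidParameterError("GAW area must be non-negative")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.area.size) / self.frame_rate


@dataclass
class CycleSet:
    """Detected oscillation cycles of a 1-D waveform.

    All index arrays have one entry per complete cycle; ``end[i] ==
    start[i+1]`` for consecutive cycles.  Phase times (seconds) are filled
    by :func:`decompose_phases` and are NaN until then.
    """

    start: np.ndarray
    max_idx: np.ndarray
    end: np.ndarray
    frame_rate: float
    a_min: np.ndarray
    a_max: np.ndarray
    t_opening: np.ndarray = field(default=None)
    t_closing: np.ndarray = field(default=None)
    t_closed: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        for name in ("start", "max_idx", "end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.a_min = np.asarray(self.a_min, dtype=float)
        self.a_max = np.asarray(self.a_max, dtype=float)
        n = self.n_cycles
        if self.t_opening is None:
            self.t_opening = np.full(n, np.nan)
            self.t_closing = np.full(n, np.nan)
            self.t_closed = np.full(n, np.nan)
        if np.any(self.start >= self.max_idx) or np.any(self.max_idx >= self.end):
            raise InvalidParameterError("cycles must satisfy start < max < end")

    @property
    def n_cycles(self) -> int:
        return self.start.size

    @property
    def periods(self) -> np.ndarray:
        """Cycle periods T_i in seconds (minimum-to-minimum)."""
        return (self.end - self.start) / self.frame_rate

    @property
    def amplitudes(self) -> np.ndarray:
        """Offset-free cycle amplitudes A_i = a_max - a_min."""
        return self.a_max - self.a_min

    @property
    def t_open(self) -> np.ndarray:
        return self.t_opening + self.t_closing

    def periods_max_to_max(self) -> np.ndarray:
        """Alternative period estimator from consecutive maxima (F0 cross-check)."""
        return np.diff(self.max_idx) / self.frame_rate


def gaw_from_masks(seg: SegmentationSequence) -> GAW:
    """Sum each binary mask into one glottal-area sample."""
    if seg.n_frames == 0:
        raise InvalidParameterError("empty mask stack")
    return GAW(seg.areas(), seg.frame_rate)


def detect_cycles(gaw: GAW, min_prominence_frac: float = 0.1) -> CycleSet:
    """Delimit complete oscillation cycles of the GAW.

    Maxima are found with prominence >= ``min_prominence_frac`` times the
    signal range; cycle boundaries sit at the minimum between consecutive
    maxima.  A signal endpoint also counts as a boundary when its value is
    down at the level of the interior minima (within 5% of the signal
    amplitude), so a recording cut exactly at closure keeps its first/last
    cycle while mid-cycle truncations are discarded as partial.
    """
    a = gaw.area
    if a.size < 3:
        raise InvalidParameterError("GAW must have at least 3 samples")
    rng = a.max() - a.min()
    if rng <= 0:
        raise TooFewCyclesError("GAW is constant; no oscillation")
    peaks, _ = sps.find_peaks(a, prominence=min_prominence_frac * rng)
    if peaks.size < 2:
        raise TooFewCyclesError(f"only {peaks.size} GAW maxima found")

    def _min_pos(seg: np.ndarray, offset: int) -> int:
        """Boundary index: middle of the run of minimum-valued samples.

        A fully closed glottis produces a flat zero plateau between
        humps; centering the boundary in the plateau keeps the period
        estimate unbiased instead of assigning the whole closed phase to
        one neighboring cycle.
        """
        at_min = np.nonzero(seg <= seg.min() + 1e-12)[0]
        return offset + int(round(at_min.mean()))

    minima = [_min_pos(a[p : q + 1], p) for p, q in zip(peaks[:-1], peaks[1:])]
    interior_level = float(np.median(a[minima]))
    tol = 0.05 * rng
    bounds = list(minima)
    if peaks[0] > 0 and a[: peaks[0]].min() <= interior_level + tol:
        bounds.insert(0, _min_pos(a[: peaks[0]], 0))
    if peaks[-1] < a.size - 1 and a[peaks[-1] :].min() <= interior_level + tol:
        bounds.append(_min_pos(a[peaks[-1] :], int(peaks[-1])))
    bounds = np.asarray(bounds, dtype=int)
    if bounds.size < 2:
        raise TooFewCyclesError("fewer than 2 cycle boundaries")

    start, end = bounds[:-1], bounds[1:]
    max_idx = np.array(
        [s + int(np.argmax(a[s : e + 1])) for s, e in zip(start, end)], dtype=int
    )
    keep = (start < max_idx) & (max_idx < end)
    if not np.any(keep):
        raise TooFewCyclesError("no complete interior cycles")
    start, end, max_idx = start[keep], end[keep], max_idx[keep]
    a_min = np.array([a[s : e + 1].min() for s, e in zip(start, end)])
    a_max = a[max_idx]
    return CycleSet(start, max_idx, end, gaw.frame_rate, a_min, a_max)


def decompose_phases(
    gaw: GAW, cycles: CycleSet, closure_eps: float = 0.02
) -> CycleSet:
    """Fill opening/closing/closed phase durations for every cycle.

    A frame counts *open* when its area exceeds the closure threshold
    ``theta_i = closure_eps * a_max_i`` (closure means the glottal area is
    a negligible fraction of the cycle peak; a waveform whose minimum
    stays above theta never closes and has ``t_closed = 0``).  Timing uses
    the threshold crossings: the opening phase runs from the last closed
    frame before the first open frame (or the cycle start) to the maximum,
    the closing phase from the maximum to the first closed frame after the
    last open frame (or the cycle end).
    """
    if not 0 <= closure_eps < 1:
        raise InvalidParameterError("closure_eps must be in [0, 1)")
    a = gaw.area
    fps = gaw.frame_rate
    n = cycles.n_cycles
    t_opening = np.empty(n)
    t_closing = np.empty(n)
    t_closed = np.empty(n)
    for i in range(n):
        s, m, e = cycles.start[i], cycles.max_idx[i], cycles.end[i]
        theta = closure_eps * cycles.a_max[i]
        seg = a[s : e + 1]
        open_idx = np.nonzero(seg > theta)[0]
        if open_idx.size == 0:  # flat cycle: everything closed
            t_opening[i] = t_closing[i] = 0.0
            t_closed[i] = (e - s) / fps
            continue
        f_open = s + open_idx[0]
        f_last = s + open_idx[-1]
        open_start = max(f_open - 1, s) if f_open > s else s
        close_end = min(f_last + 1, e)
        t_opening[i] = (m - open_start) / fps
        t_closing[i] = (close_end - m) / fps
        t_closed[i] = (e - s) / fps - t_opening[i] - t_closing[i]
    cycles.t_opening = t_opening
    cycles.t_closing = t_closing
    cycles.t_closed = np.maximum(t_closed, 0.0)
    return cycles
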