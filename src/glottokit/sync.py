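"""Audio-video alignment from the camera reference (Synch Out) channel.

High-speed cameras emit one electrical pulse per recorded frame on a
reference output that is digitized alongside the subject microphone.  The
recording ends with an external trigger, after which the audio interface
keeps recording (typically one extra second) while the reference channel
goes quiet.  Locating that pulsed-to-quiescent transition (the *end
trigger*) and every per-frame pulse before it yields an exact mapping from
video frame indices to audio sample indices.

The detection pipeline is: rolling standard deviation of the raw reference
signal (2.5 ms window) -> z-score -> locate the most prominent transition
-> per-frame peak picking before the trigger.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientPulsesError,
    InvalidParameterError,
    TriggerNotFoundError,
)

log = logging.getLogger(__name__)

__all__ = [
    "TwoChannelRecording",
    "AlignmentResult",
    "rolling_std",
    "detect_end_trigger",
    "detect_frame_pulses",
    "extract_audio_segment",
]


@dataclass
class TwoChannelRecording:
    """Microphone + camera-reference recording.

    Parameters
    ----------
    audio : ndarray
        Subject microphone samples, dimensionless amplitude in [-1, 1].
    reference : ndarray
        Camera reference-pulse samples, same length as ``audio``.
    sample_rate : float
        Sampling rate in Hz (default 80 kHz).
    bit_depth : int
        Original quantization of the recording (metadata only).
    """

    audio: np.ndarray
    reference: np.ndarray
    sample_rate: float = 80_000.0
    bit_depth: int = 24

    def __post_init__(self) -> None:
        self.audio = np.asarray(self.audio, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.audio.shape != self.reference.shape or self.audio.ndim != 1:
            raise InvalidParameterError(
                "audio and reference must be 1-D arrays of equal length"
            )
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.audio.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class AlignmentResult:
    """Mapping between video frames and audio samples.

    ``frame_pulse_samples[k]`` is the audio sample index at which frame *k*
    starts; ``samples_per_frame`` is the nominal spacing
    ``sample_rate / fps``.
    """

    end_trigger_sample: int
    frame_pulse_samples: np.ndarray
    samples_per_frame: float
    n_frames_detected: int = field(default=0)

    def __post_init__(self) -> None:
        self.frame_pulse_samples = np.asarray(self.frame_pulse_samples, dtype=int)
        if np.any(np.diff(self.frame_pulse_samples) <= 0):
            raise InvalidParameterError("frame pulses must be strictly increasing")
        if self.frame_pulse_samples.size and (
            self.frame_pulse_samples[-1] > self.end_trigger_sample
        ):
            raise InvalidParameterError("pulses must not lie beyond the end trigger")
        self.n_frames_detected = int(self.frame_pulse_samples.size)

    def to_dict(self) -> dict:
        return {
            "end_trigger_sample": int(self.end_trigger_sample),
            "frame_pulse_samples": self.frame_pulse_samples.tolist(),
            "samples_per_frame": float(self.samples_per_frame),
            "n_frames_detected": self.n_frames_detected,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentResult":
        return cls(
            end_trigger_sample=int(d["end_trigger_sample"]),
            frame_pulse_samples=np.asarray(d["frame_pulse_samples"], dtype=int),
            samples_per_frame=float(d["samples_per_frame"]),
        )


def _window_samples(window_ms: float, sample_rate: float) -> int:
    n = int(round(window_ms * 1e-3 * sample_rate))
    if n < 2:
        raise InvalidParameterError(
            f"rolling window of {window_ms} ms is shorter than 2 samples "
            f"at {sample_rate} Hz"
        )
    return n


def rolling_std(
    x: np.ndarray, window_ms: float = 2.5, sample_rate: float = 80_000.0
) -> np.ndarray:
    """Centered rolling standard deviation with shrunken edge windows.

    Element *i* holds the population std of the samples in the window
    centered at *i*; near the edges the window shrinks rather than padding
    with invented values.  Length is preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidParameterError("signal is empty")
    w = _window_samples(window_ms, sample_rate)
    half_lo, half_hi = w // 2, w - w // 2  # window = [i - half_lo, i + half_hi)
    x = x - x.mean()  # std is shift-invariant; centering avoids cancellation
    # cumulative sums with a leading zero give O(n) windowed moments
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, x.size)
    n = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = s2 / n - (s1 / n) ** 2
    return np.sqrt(np.maximum(var, 0.0))


def detect_end_trigger(
    recording: TwoChannelRecording,
    window_ms: float = 2.5,
    prominence: float = 1.0,
) -> int:
    """Locate the end trigger: where the reference pulse train ceases.

    The rolling std of the reference is z-scored; the transition is the
    most prominent peak of the window-lagged falling difference
    ``z[i] - z[i+w]`` (a downward step becomes a clean triangular peak,
    and pulse-train onsets are ignored).  If no
    peak reaches ``prominence``, the last sample whose rolling std exceeds
    half its robust maximum is used.  A quiescent tail after the candidate
    is required; otherwise :class:`TriggerNotFoundError` is raised.
    """
    ref = recording.reference
    w = _window_samples(window_ms, recording.sample_rate)
    rs = rolling_std(ref, window_ms, recording.sample_rate)
    rs_std = rs.std()
    if rs_std == 0 or rs.size <= 2 * w:
        raise TriggerNotFoundError("reference channel has no pulse activity")
    z = (rs - rs.mean()) / rs_std

    # signed falling-edge detector: positive only where activity drops
    lagged = z[:-w] - z[w:]
    peaks, props = sps.find_peaks(lagged, prominence=prominence)
    if peaks.size:
        best = peaks[np.argmax(props["prominences"])]
        trigger = int(best + w // 2)
    else:
        level = 0.5 * np.percentile(rs, 99.9)
        above = np.nonzero(rs > level)[0]
        if above.size == 0:
            raise TriggerNotFoundError("reference channel has no pulse activity")
        trigger = int(above[-1])

    # the pulse train must actually stop: demand a quiescent tail
    tail = rs[min(trigger + w, rs.size):]
    head = rs[:max(trigger - w, 1)]
    if tail.size < w or head.size < w or tail.mean() > 0.25 * head.mean():
        raise TriggerNotFoundError(
            "no quiescent tail after candidate trigger "
            f"(sample {trigger}); reference may be fully pulsed or flat"
        )
    return trigger


def detect_frame_pulses(
    recording: TwoChannelRecording,
    end_trigger: int,
    fps: float = 4000.0,
    height_frac: float = 0.5,
) -> AlignmentResult:
    """Detect one reference peak per recorded camera frame.

    Peaks are searched on the raw reference up to ``end_trigger`` with a
    minimum spacing of half the nominal frame interval and a height of
    ``height_frac`` times the 99th-percentile pre-trigger amplitude.
    Pulse polarity is auto-detected from the dominant excursion sign.
    """
    if not 0 < end_trigger <= recording.n_samples:
        raise InvalidParameterError("end_trigger outside recording")
    if fps <= 0:
        raise InvalidParameterError("fps must be positive")
    nominal = recording.sample_rate / fps
    ref = recording.reference[: end_trigger + 1]
    if np.abs(ref.min()) > np.abs(ref.max()):  # negative-going pulses
        ref = -ref
    height = height_frac * np.percentile(np.abs(ref), 99)
    # pad with the baseline level so pulses at the very first/last sample
    # (plateaus at the array edge) are still detected as peaks
    base = np.percentile(ref, 1)
    padded = np.concatenate(([base], ref, [base]))
    peaks, _ = sps.find_peaks(
        padded, distance=max(int(0.5 * nominal), 1), height=height
    )
    peaks = peaks - 1
    if peaks.size < 2:
        raise InsufficientPulsesError(
            f"only {peaks.size} reference pulse(s) found before the trigger"
        )
    measured = float(np.median(np.diff(peaks)))
    if abs(measured - nominal) / nominal > 0.02:
        warnings.warn(
            f"median pulse spacing {measured:.2f} samples deviates >2% from "
            f"nominal {nominal:.2f} (sample_rate/fps); check fps metadata",
            stacklevel=2,
        )
    return AlignmentResult(
        end_trigger_sample=int(end_trigger),
        frame_pulse_samples=peaks,
        samples_per_frame=nominal,
    )


def extract_audio_segment(
    recording: TwoChannelRecording,
    alignment: AlignmentResult,
    first_frame: int,
    last_frame: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Audio samples spanning frames ``first_frame..last_frame`` inclusive.

    Returns ``(samples, (start, stop))`` with ``stop`` exclusive; the last
    frame contributes one nominal frame duration beyond its pulse.
    """
    n = alignment.n_frames_detected
    if not (0 <= first_frame <= last_frame < n):
        raise IndexError(
            f"frame range {first_frame}..{last_frame} outside 0..{n - 1}"
        )
    start = int(alignment.frame_pulse_samples[first_frame])
    stop = int(
        round(alignment.frame_pulse_samples[last_frame] + alignment.samples_per_frame)
    )
    stop = min(stop, recording.n_samples)
    return recording.audio[start:stop], (start, stop)
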