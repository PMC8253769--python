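"""Ground-truthed synthetic phonation recordings.

Generates the three coupled signals a high-speed videoendoscopy session
produces -- an oscillating-glottis movie with exact segmentation masks, a
paired acoustic waveform sharing the same per-cycle periods and
amplitudes, and the camera reference-pulse channel with an end trigger --
so every pipeline stage can be exercised and validated without hardware.

The vibration model is a per-cycle template: each cycle draws a period
(mean 1/F0, Gaussian jitter) and an amplitude (mean 1, Gaussian shimmer);
within a cycle the glottal area follows a skewed raised-sinusoid hump
whose peak position encodes the speed-index target and whose open
fraction encodes the open-quotient target, above a relative area floor
(the glottal-gap target: a floor above the closure threshold means the
glottis never fully closes, as is typical for healthy phonation).  Left
and right vocal folds get separate amplitude scales and a phase lag to
set the symmetry-index targets.  The acoustic channel is a
Rosenberg-type glottal pulse train (no vocal-tract filter) driven by the
same cycle sequence.

Defaults reproduce a healthy sustained phonation: F0 250 Hz, 4000 fps,
80 kHz audio, 1000 frames (0.25 s), area floor 0.15, left/right amplitude
ratio 0.97, phase lag 0.02 of a period, jitter sigma 70 us, shimmer sigma
2%, audio SNR 40 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidParameterError
from .segmentation import SegmentationSequence, VideoFrames
from .sync import TwoChannelRecording

__all__ = ["PhonationSpec", "Schedule", "synth_gaw_schedule", "render_video", "render_audio"]


@dataclass
class PhonationSpec:
    """Parameters of one synthetic phonation recording."""

    f0: float = 250.0                  # Hz
    duration: float = 0.25             # s of video
    fps: float = 4000.0
    audio_rate: float = 80_000.0
    open_quotient_target: float = 1.0  # open fraction of the cycle (floor = 0)
    speed_index_target: float = 0.0    # (t_opening - t_closing)/t_open
    left_right_amp_ratio: float = 0.97
    left_right_phase_lag: float = 0.02  # fraction of a period
    jitter_sigma: float = 70e-6        # s, per-cycle period perturbation
    shimmer_sigma: float = 0.02        # relative amplitude perturbation
    glottal_floor: float = 0.15        # minimal opening relative to peak (GGI)
    image_size: int = 256              # px (square frames)
    midline_angle: float = 0.0         # degrees from vertical
    noise: float = 5.0                 # pixel noise sigma, 8-bit counts
    audio_snr_db: float = 40.0
    seed: int = 0
    peak_area_frac: float = 0.04       # peak glottal area as fraction of frame

    def __post_init__(self) -> None:
        if min(self.f0, self.duration, self.fps, self.audio_rate) <= 0:
            raise InvalidParameterError("rates and duration must be positive")
        if not 0 < self.open_quotient_target <= 1:
            raise InvalidParameterError("open_quotient_target must be in (0, 1]")
        if not -1 < self.speed_index_target < 1:
            raise InvalidParameterError(
                "speed_index_target must be strictly inside (-1, 1)"
            )
        if not 0 < self.left_right_amp_ratio <= 1:
            raise InvalidParameterError("left_right_amp_ratio must be in (0, 1]")
        if not 0 <= self.glottal_floor < 1:
            raise InvalidParameterError("glottal_floor must be in [0, 1)")
        if self.duration * self.f0 < 3:
            raise InvalidParameterError("need at least 3 cycles of phonation")


@dataclass
class Schedule:
    """Per-frame areas plus per-cycle ground truth."""

    spec: PhonationSpec
    cycle_starts: np.ndarray       # s, start time of each cycle
    periods: np.ndarray            # s, per cycle
    amplitudes: np.ndarray         # relative, per cycle
    left_area: np.ndarray          # px^2 per frame
    right_area: np.ndarray        # px^2 per frame
    targets: dict = field(default_factory=dict)

    @property
    def area(self) -> np.ndarray:
        return self.left_area + self.right_area

    @property
    def n_frames(self) -> int:
        return self.left_area.size


def _hump(tau: np.ndarray, q: float) -> np.ndarray:
    """Skewed raised-sinusoid pulse: 0 at tau=0/1, 1 at tau=q."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    rise = (tau >= 0) & (tau < q)
    fall = (tau >= q) & (tau <= 1)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * tau[rise] / q))
    out[fall] = 0.5 * (1.0 + np.cos(np.pi * (tau[fall] - q) / (1.0 - q)))
    return out


def _template(tau: np.ndarray, oq: float, q: float, floor: float) -> np.ndarray:
    """Cycle waveform in [floor, 1]: hump over the open fraction, floor after."""
    tau = np.mod(tau, 1.0)
    y = np.where(tau < oq, _hump(tau / oq, q), 0.0)
    return floor + (1.0 - floor) * y


def _cycle_phase(
    t: np.ndarray, starts: np.ndarray, periods: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
    tau = (t - starts[idx]) / periods[idx]
    return idx, tau


def synth_gaw_schedule(spec: PhonationSpec) -> Schedule:
    """Draw the per-cycle sequence and sample per-frame hemi areas.

    Ground-truth targets (what the pipeline should recover) are attached:
    F0, effective open quotient (1.0 when the floor keeps the glottis off
    the closure threshold), speed index, glottal gap index, amplitude
    symmetry and phase asymmetry, plus the realized per-cycle period and
    amplitude draws for perturbation-recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    T0 = 1.0 / spec.f0
    n_cycles = int(np.ceil(spec.duration / T0)) + 3
    periods = T0 + rng.normal(0.0, spec.jitter_sigma, n_cycles)
    periods = np.clip(periods, 0.5 * T0, 1.5 * T0)
    amps = np.clip(1.0 + rng.normal(0.0, spec.shimmer_sigma, n_cycles), 0.2, None)
    starts = np.concatenate(([0.0], np.cumsum(periods[:-1])))

    n_frames = int(round(spec.duration * spec.fps))
    t = np.arange(n_frames) / spec.fps
    idx, tau = _cycle_phase(t, starts, periods)

    q = (1.0 + spec.speed_index_target) / 2.0
    oq, floor = spec.open_quotient_target, spec.glottal_floor
    peak_area = spec.peak_area_frac * spec.image_size**2
    scale = peak_area / (1.0 + spec.left_right_amp_ratio)
    y_r = _template(tau, oq, q, floor)
    y_l = _template(tau - spec.left_right_phase_lag, oq, q, floor)
    right = scale * amps[idx] * y_r
    left = scale * spec.left_right_amp_ratio * amps[idx] * y_l

    # effective targets from the continuous cycle construction: with a
    # left-right phase lag the *summed* area differs from the single-fold
    # template (its minimum rises above the floor, its peak shifts), so
    # ground truth is evaluated analytically on a fine phase grid rather
    # than echoing the nominal spec fields
    closure_eps = 0.02  # default closure threshold of the phase decomposition
    tau_f = np.linspace(0.0, 1.0, 8192, endpoint=False)
    a_r = _template(tau_f, oq, q, floor)
    a_l = spec.left_right_amp_ratio * _template(
        tau_f - spec.left_right_phase_lag, oq, q, floor
    )
    a_tot = a_r + a_l
    # measure the cycle from its actual minimum (the lag shifts it off tau=0)
    a_tot = np.roll(a_tot, -int(np.argmin(a_tot)))
    theta = closure_eps * a_tot.max()
    open_idx = np.nonzero(a_tot > theta)[0]
    pk = int(np.argmax(a_tot))
    if open_idx.size == tau_f.size:  # never closes
        oq_eff, opening, closing = 1.0, tau_f[pk], 1.0 - tau_f[pk]
    else:
        oq_eff = open_idx.size / tau_f.size
        opening = tau_f[pk] - tau_f[open_idx[0]]
        closing = tau_f[open_idx[-1]] - tau_f[pk]
    lag_pk = (np.argmax(a_l) - np.argmax(a_r)) / tau_f.size % 1.0
    targets = {
        "f0": spec.f0,
        "open_quotient": float(oq_eff),
        "speed_index": float((opening - closing) / max(opening + closing, 1e-12)),
        "glottal_gap_index": float(a_tot.min() / a_tot.max()),
        "amplitude_symmetry_index": float(
            min(a_l.max() - a_l.min(), a_r.max() - a_r.min())
            / max(a_l.max() - a_l.min(), a_r.max() - a_r.min())
        ),
        "phase_asymmetry_index": float(min(lag_pk, 1.0 - lag_pk)),
        "jitter_mean_abs_dT_ms": float(np.mean(np.abs(np.diff(periods))) * 1e3),
        "shimmer_pct": float(
            100.0 * np.mean(np.abs(np.diff(amps))) / np.mean(amps)
        ),
    }
    return Schedule(
        spec=spec,
        cycle_starts=starts,
        periods=periods,
        amplitudes=amps,
        left_area=left,
        right_area=right,
        targets=targets,
    )


def _geometry(spec: PhonationSpec):
    S = spec.image_size
    alpha = np.deg2rad(spec.midline_angle)
    u = np.array([np.sin(alpha), np.cos(alpha)])   # posterior(top) -> anterior
    w = np.array([u[1], -u[0]])                    # positive = image right
    center = np.array([S / 2.0, S / 2.0])
    length = 0.6 * S
    posterior = center - 0.5 * length * u
    return u, w, posterior, length


def render_video(
    spec: PhonationSpec,
    schedule: Schedule,
    masks_only: bool = False,
) -> tuple[Optional[VideoFrames], SegmentationSequence]:
    """Rasterize the schedule into frames and exact ground-truth masks.

    The glottis is a dark lens: two opposed parabolic edges about a
    midline at ``midline_angle``, the lateral half-width of each fold
    scaled so that the rasterized side areas match the schedule's hemi
    areas (displacement vanishes at the anterior/posterior endpoints).
    Frames show the lens (intensity ~20) on bright tissue carrying
    multi-scale mucosa-like texture, band-limited by an optics-like
    point-spread blur, with additive Gaussian pixel noise.  With ``masks_only`` the
    (expensive) intensity rendering is skipped and only masks return.
    """
    S = spec.image_size
    if S < 32:
        raise InvalidParameterError("image_size must be >= 32 px")
    u, w, posterior, length = _geometry(spec)
    yy, xx = np.mgrid[0:S, 0:S]
    px = xx - posterior[0]
    py = yy - posterior[1]
    p = (px * u[0] + py * u[1]) / length
    s = px * w[0] + py * w[1]
    g = np.where((p >= 0) & (p <= 1), 4.0 * p * (1.0 - p), -1.0)

    n = schedule.n_frames
    w_l = 1.5 * schedule.left_area / length
    w_r = 1.5 * schedule.right_area / length
    if max(w_l.max(), w_r.max()) > 0.45 * S:
        raise InvalidParameterError("image too small for the requested glottis")
    masks = np.empty((n, S, S), dtype=np.uint8)
    for k in range(n):
        # strict comparisons: a zero-width (closed) glottis rasterizes empty
        masks[k] = (g > 0) & (s < w_r[k] * g) & (s > -w_l[k] * g)
    seg = SegmentationSequence(masks, spec.fps)
    if masks_only:
        return None, seg

    rng = np.random.default_rng(spec.seed + 101)
    # multi-scale mucosa-like texture (vasculature down to fine detail)
    from .quality import fractal_texture

    tissue = np.clip(175.0 + 18.0 * fractal_texture(rng, S, jitter=False), 60, 255)
    frames = np.where(masks.astype(bool), 20.0, tissue[None])
    # optics point-spread: endoscope + lens band-limit the image
    frames = gaussian_filter(frames, sigma=(0.0, 0.5, 0.5))
    if spec.noise > 0:
        frames = frames + rng.normal(0.0, spec.noise, frames.shape)
    video = VideoFrames(
        np.clip(frames, 0, 255).astype(np.uint8), spec.fps
    )
    return video, seg


def _rosenberg(t_in_cycle: np.ndarray, t_rise: float, t_fall: float) -> np.ndarray:
    """Rosenberg glottal flow pulse, fixed open time in seconds.

    The pulse shape is identical in every cycle (rise ``t_rise``, fall
    ``t_fall``, then closed); period perturbation only stretches the
    closed phase, as for a source whose open time is set by fold
    mechanics rather than by the instantaneous period.
    """
    out = np.zeros_like(t_in_cycle)
    rise = (t_in_cycle >= 0) & (t_in_cycle < t_rise)
    fall = (t_in_cycle >= t_rise) & (t_in_cycle < t_rise + t_fall)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * t_in_cycle[rise] / t_rise))
    out[fall] = np.cos(0.5 * np.pi * (t_in_cycle[fall] - t_rise) / t_fall)
    return out


def render_audio(
    spec: PhonationSpec, schedule: Schedule
) -> tuple[TwoChannelRecording, dict]:
    """Paired microphone + camera-reference channels with ground truth.

    Channel 0 carries a Rosenberg glottal-pulse voice signal sharing the
    schedule's per-cycle periods and amplitudes, plus white noise at the
    spec's SNR.  Channel 1 carries one short rectangular pulse per video
    frame at ``audio_rate / fps`` spacing, ceasing at the end trigger,
    followed by one second of silence (the audio interface keeps rolling
    after the camera stops).  Returns the recording and a ground-truth
    dict with the true frame-pulse sample indices, trigger sample and
    per-cycle peak times of the voice waveform.
    """
    sr = spec.audio_rate
    spf = sr / spec.fps
    n_frames = schedule.n_frames
    n_voice = int(round(n_frames * spf))
    n_total = n_voice + int(sr)  # one extra second after the trigger
    rng = np.random.default_rng(spec.seed + 211)

    t = np.arange(n_voice) / sr
    idx, tau = _cycle_phase(t, schedule.cycle_starts, schedule.periods)
    T0 = 1.0 / spec.f0
    t_rise, t_fall = 0.40 * T0, 0.16 * T0
    t_in_cycle = tau * schedule.periods[idx]
    voice = schedule.amplitudes[idx] * _rosenberg(t_in_cycle, t_rise, t_fall)
    # broadband excitation at glottal closure (the dominant acoustic event):
    # gives the waveform the full harmonic comb a real voice carries, which
    # the smooth flow pulse alone lacks
    shock = 2.0
    closure_samples = np.round((schedule.cycle_starts + t_rise + t_fall) * sr).astype(int)
    ok = (closure_samples > 0) & (closure_samples < n_voice - 1)
    voice[closure_samples[ok]] -= shock * schedule.amplitudes[ok]
    voice *= 0.5 / np.max(np.abs(voice))
    audio = np.zeros(n_total)
    audio[:n_voice] = voice
    rms = np.sqrt(np.mean(voice**2))
    noise_sigma = rms * 10 ** (-spec.audio_snr_db / 20.0)
    if noise_sigma > 0:
        audio += rng.normal(0.0, noise_sigma, n_total)

    reference = rng.normal(0.0, 0.002, n_total)
    pulse_samples = np.round(np.arange(n_frames) * spf).astype(int)
    for off in range(3):  # 3-sample rectangular pulses
        reference[pulse_samples + off] += 0.9
    trigger = int(pulse_samples[-1])

    rec = TwoChannelRecording(audio=audio, reference=reference, sample_rate=sr)
    peak_times = schedule.cycle_starts + t_rise  # pulse peak, fixed open time
    truth = {
        "frame_pulse_samples": pulse_samples,
        "end_trigger_sample": trigger,
        "n_frames": n_frames,
        "voice_peak_times": peak_times[peak_times < n_voice / sr],
        "n_voice_samples": n_voice,
    }
    return rec, truth
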