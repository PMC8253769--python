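"""Clinical voice parameters from the GAW, hemi-GAWs and audio signal.

Cycle-based measures (F0, jitter, shimmer, phase quotients, perturbation
quotients, symmetry indices) are computed per cycle and averaged; the
whole audio segment feeds the harmonics-to-noise ratio (HNR, Yumoto
method) and the cepstral peak prominence (CPP).  The same period/amplitude
formulas apply to cycles detected on the glottal area waveform and to
cycles detected on the acoustic waveform, so video- and audio-derived
perturbation measures are directly comparable.

Every formula is identified by a ``formula_id`` emitted into the report
so downstream CSV files are self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import signal as sps

from .errors import (
    InvalidParameterError,
    TooFewCyclesError,
    UndefinedMeasureError,
)
from .midline import HemiGAW
from .waveform import GAW, CycleSet

__all__ = [
    "AudioCycles",
    "ParameterReport",
    "detect_audio_cycles",
    "fundamental_frequency",
    "jitter",
    "shimmer",
    "phase_quotients",
    "glottal_gap_index",
    "amplitude_quotient",
    "stiffness",
    "symmetry_indices",
    "amplitude_perturbation",
    "hnr",
    "cpp",
    "compute_report",
]


@runtime_checkable
class Cycles(Protocol):
    """Anything exposing per-cycle periods (s) and amplitudes."""

    @property
    def periods(self) -> np.ndarray: ...

    @property
    def amplitudes(self) -> np.ndarray: ...


@dataclass
class AudioCycles:
    """Cycles detected on the acoustic waveform.

    peak_times : refined (sub-sample) cycle peak instants in seconds
    peak_samples : integer peak sample indices into the analyzed signal
    cycle_amplitudes : per-cycle peak-to-following-trough amplitudes
    """

    peak_times: np.ndarray
    peak_samples: np.ndarray
    cycle_amplitudes: np.ndarray
    sample_rate: float
    f0_prior: float

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.peak_times)

    @property
    def amplitudes(self) -> np.ndarray:
        return self.cycle_amplitudes

    @property
    def n_cycles(self) -> int:
        return self.periods.size


def _parabolic_refine(y: np.ndarray, k: int) -> float:
    """Sub-sample vertex of the parabola through y[k-1], y[k], y[k+1]."""
    if k <= 0 or k >= y.size - 1:
        return float(k)
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom == 0:
        return float(k)
    dx = 0.5 * (y[k - 1] - y[k + 1]) / denom
    return float(k + np.clip(dx, -1, 1))


def _autocorr_f0(
    x: np.ndarray, sample_rate: float, f0_range: tuple[float, float]
) -> float:
    """Fundamental-frequency prior from the biased autocorrelation."""
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:n]
    lag_lo = max(int(sample_rate / f0_range[1]), 1)
    lag_hi = min(int(sample_rate / f0_range[0]), n - 2)
    if lag_hi <= lag_lo:
        raise UndefinedMeasureError("signal too short for the F0 search range")
    k = lag_lo + int(np.argmax(r[lag_lo : lag_hi + 1]))
    lag = _parabolic_refine(r, k)
    if r[k] <= 0:
        raise UndefinedMeasureError("no periodicity in the F0 search range")
    return sample_rate / lag


def detect_audio_cycles(
    audio: np.ndarray,
    sample_rate: float,
    f0_range: tuple[float, float] = (60.0, 500.0),
) -> AudioCycles:
    """Detect individual acoustic cycles for jitter/shimmer/F0.

    An autocorrelation F0 prior gates peak picking: the signal is low-pass
    filtered at 4x the prior (removing wide-band noise while preserving
    the per-cycle pulse shape), peaks are picked with a minimal spacing of
    0.6 periods, and peak instants are refined by parabolic interpolation
    for sub-sample period resolution.  Per-cycle amplitudes are measured
    peak-to-following-trough on the filtered signal.
    """
    x = np.asarray(audio, dtype=float)
    if x.size < 16 or np.all(x == x[0]):
        raise UndefinedMeasureError("audio signal is too short or silent")
    f0 = _autocorr_f0(x, sample_rate, f0_range)
    fc = min(4.0 * f0, 0.45 * sample_rate)
    sos = sps.butter(4, fc, btype="low", fs=sample_rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    period = sample_rate / f0
    prominence = 0.3 * (np.percentile(y, 98) - np.percentile(y, 2))
    peaks, _ = sps.find_peaks(y, distance=max(int(0.6 * period), 1),
                              prominence=prominence)
    if peaks.size < 2:
        raise TooFewCyclesError(f"only {peaks.size} acoustic cycle peak(s) found")
    refined = np.array([_parabolic_refine(y, int(k)) for k in peaks])
    amps = np.empty(peaks.size)
    for i, k in enumerate(peaks):
        nxt = peaks[i + 1] if i + 1 < peaks.size else min(k + int(1.5 * period), y.size)
        trough = y[k:nxt].min() if nxt > k else y[k]
        amps[i] = y[k] - trough
    # one amplitude per complete cycle (peak i owns cycle i)
    return AudioCycles(
        peak_times=refined / sample_rate,
        peak_samples=peaks,
        cycle_amplitudes=amps[:-1] if peaks.size > 2 else amps[: peaks.size - 1],
        sample_rate=sample_rate,
        f0_prior=f0,
    )


def _require_cycles(cycles: Cycles, n: int, what: str) -> None:
    if cycles.periods.size < n:
        raise TooFewCyclesError(
            f"{what} needs >= {n} cycles, got {cycles.periods.size}"
        )


def fundamental_frequency(cycles: Cycles) -> float:
    """F0 = 1 / mean cycle period, in Hz."""
    _require_cycles(cycles, 2, "fundamental_frequency")
    return float(1.0 / np.mean(cycles.periods))


def jitter(cycles: Cycles) -> tuple[float, float]:
    """(mean jitter in ms, jitter in %) from consecutive period differences."""
    _require_cycles(cycles, 2, "jitter")
    T = cycles.periods
    dT = np.abs(np.diff(T))
    return float(dT.mean() * 1e3), float(100.0 * dT.mean() / T.mean())


def shimmer(cycles: Cycles) -> tuple[float, float]:
    """(mean shimmer in dB, shimmer in %) from consecutive amplitudes."""
    _require_cycles(cycles, 2, "shimmer")
    A = cycles.amplitudes
    if np.any(A <= 0):
        raise InvalidParameterError("shimmer requires strictly positive amplitudes")
    ratios = np.abs(20.0 * np.log10(A[1:] / A[:-1]))
    dA = np.abs(np.diff(A))
    return float(ratios.mean()), float(100.0 * dA.mean() / A.mean())


def phase_quotients(cycles: CycleSet) -> dict[str, float]:
    """Phase-duration quotients averaged over cycles.

    Per cycle: OQ = t_open/T, CQ = t_closing/t_open, SQ =
    t_opening/t_closing, AQ = t_opening/t_open, RQ = (t_closed +
    t_opening)/t_closing, SI = (t_opening - t_closing)/t_open.  Cycles
    with a zero closing phase are excluded from CQ/SQ/RQ with a warning.
    """
    if np.any(np.isnan(cycles.t_opening)):
        raise InvalidParameterError("run decompose_phases before phase_quotients")
    T = cycles.periods
    to, tc, tcl = cycles.t_opening, cycles.t_closing, cycles.t_closed
    topen = to + tc
    ok_open = topen > 0
    oq = np.mean(topen[ok_open] / T[ok_open])
    si = np.mean((to[ok_open] - tc[ok_open]) / topen[ok_open])
    aq = np.mean(to[ok_open] / topen[ok_open])
    ok = ok_open & (tc > 0)
    if not np.all(ok):
        warnings.warn(
            f"{np.count_nonzero(~ok)} cycle(s) with zero closing phase "
            "excluded from CQ/SQ/RQ",
            stacklevel=2,
        )
    if not np.any(ok):
        raise UndefinedMeasureError("no cycle has a nonzero closing phase")
    cq = np.mean(tc[ok] / topen[ok])
    sq = np.mean(to[ok] / tc[ok])
    rq = np.mean((tcl[ok] + to[ok]) / tc[ok])
    return {
        "open_quotient": float(oq),
        "closing_quotient": float(cq),
        "speed_quotient": float(sq),
        "asymmetry_quotient": float(aq),
        "rate_quotient": float(rq),
        "speed_index": float(si),
    }


def glottal_gap_index(cycles: CycleSet) -> float:
    """GGI = mean of a_min/a_max per cycle (residual opening at closure)."""
    ok = cycles.a_max > 0
    if not np.any(ok):
        raise UndefinedMeasureError("all cycles have zero maximum area")
    return float(np.mean(cycles.a_min[ok] / cycles.a_max[ok]))


def amplitude_quotient(gaw: GAW, cycles: CycleSet) -> float:
    """AQamp = A_i / |steepest per-frame area decline|, mean over cycles.

    The unit is frames (time steps), i.e. dimensionless 'au' at fixed fps.
    """
    vals = []
    for i in range(cycles.n_cycles):
        seg = gaw.area[cycles.start[i] : cycles.end[i] + 1]
        d = np.diff(seg)
        dmin = d.min()
        if dmin >= 0:
            continue  # no declining sample: cycle excluded
        vals.append(cycles.amplitudes[i] / abs(dmin))
    if not vals:
        raise UndefinedMeasureError("no cycle with a declining area derivative")
    return float(np.mean(vals))


def stiffness(gaw: GAW, cycles: CycleSet) -> float:
    """Mean |per-frame area change| normalized by cycle amplitude."""
    vals = []
    for i in range(cycles.n_cycles):
        A = cycles.amplitudes[i]
        if A <= 0:
            continue
        seg = gaw.area[cycles.start[i] : cycles.end[i] + 1]
        vals.append(np.abs(np.diff(seg)).mean() / A)
    if not vals:
        raise UndefinedMeasureError("no cycle with nonzero amplitude")
    return float(np.mean(vals))


def symmetry_indices(hemi: HemiGAW, cycles: CycleSet) -> tuple[float, float]:
    """(ASI, PAI): left/right amplitude ratio and normalized peak-time lag.

    Per cycle, hemi amplitudes are max-min of each hemi-GAW within the
    cycle and hemi peak times are parabolic-refined argmax instants; ASI =
    min/max amplitude ratio (1 = symmetric), PAI = |t_left - t_right| / T
    wrapped to [0, 0.5].  Cycles with a zero hemi amplitude are excluded.
    """
    asi_vals, pai_vals = [], []
    fps = cycles.frame_rate
    for i in range(cycles.n_cycles):
        s, e = cycles.start[i], cycles.end[i]
        L = hemi.left_area[s : e + 1]
        R = hemi.right_area[s : e + 1]
        AL, AR = L.max() - L.min(), R.max() - R.min()
        if AL <= 0 or AR <= 0:
            continue
        tL = _parabolic_refine(L, int(np.argmax(L))) / fps
        tR = _parabolic_refine(R, int(np.argmax(R))) / fps
        T = (e - s) / fps
        lag = abs(tL - tR) / T % 1.0
        pai_vals.append(min(lag, 1.0 - lag))
        asi_vals.append(min(AL, AR) / max(AL, AR))
    if not asi_vals:
        raise UndefinedMeasureError("no cycle with nonzero hemi amplitudes")
    return float(np.mean(asi_vals)), float(np.mean(pai_vals))


def amplitude_perturbation(
    cycles: Cycles, windows: Sequence[int] = (3, 5, 11)
) -> dict[str, Optional[float]]:
    """APF and windowed amplitude perturbation quotients (percent).

    APF = 100 * mean |A_i - A_{i+1}| / A_i; APQk = 100 * mean over valid
    centers of |A_i - mean(k-window centered at i)| / mean(all A).  A
    window larger than the cycle count yields ``None`` for that APQk.
    """
    A = np.asarray(cycles.amplitudes, dtype=float)
    if A.size < 2:
        raise TooFewCyclesError("amplitude perturbation needs >= 2 cycles")
    if np.any(A <= 0):
        raise InvalidParameterError("amplitudes must be strictly positive")
    out: dict[str, Optional[float]] = {
        "apf": float(100.0 * np.mean(np.abs(A[:-1] - A[1:]) / A[:-1]))
    }
    mean_all = A.mean()
    for k in windows:
        if k % 2 == 0 or k < 3:
            raise InvalidParameterError("APQ windows must be odd and >= 3")
        if A.size < k:
            out[f"apq{k}"] = None
            continue
        half = k // 2
        devs = [
            abs(A[i] - A[i - half : i + half + 1].mean())
            for i in range(half, A.size - half)
        ]
        out[f"apq{k}"] = float(100.0 * np.mean(devs) / mean_all)
    return out


def hnr(
    audio: np.ndarray,
    cycles: AudioCycles,
    cap_db: float = 120.0,
) -> float:
    """Harmonics-to-noise ratio (dB), Yumoto ensemble method.

    Each detected cycle is resampled to the mean cycle length L; with mean
    waveform f_bar over N cycles, HNR = 10 log10( N * sum f_bar^2 /
    sum_i sum_t (f_i - f_bar)^2 ).  A zero residual (perfectly periodic
    signal) is capped at ``cap_db``.
    """
    x = np.asarray(audio, dtype=float)
    if np.allclose(x, 0):
        raise UndefinedMeasureError("silent signal has no HNR")
    peaks = cycles.peak_samples
    if peaks.size < 6:
        raise TooFewCyclesError("HNR needs >= 5 complete cycles")
    lengths = np.diff(peaks)
    L = int(round(lengths.mean()))
    grid = np.arange(L) / L
    ens = np.stack(
        [
            np.interp(grid * (b - a), np.arange(b - a + 1), x[a : b + 1])
            for a, b in zip(peaks[:-1], peaks[1:])
        ]
    )
    fbar = ens.mean(axis=0)
    num = ens.shape[0] * np.sum(fbar**2)
    den = np.sum((ens - fbar) ** 2)
    if den == 0:
        return float(cap_db)
    return float(min(10.0 * np.log10(num / den), cap_db))


def _power_cepstrum(
    x: np.ndarray,
    sample_rate: float,
    work_rate: float = 10_000.0,
    frame: int = 1024,
    smooth: int = 5,
) -> tuple[np.ndarray, float]:
    """Frame-averaged power cepstrum of the whole signal, in dB.

    The signal is decimated to a voice-band working rate (cepstral voice
    analysis convention: the harmonic comb must occupy a substantial part
    of the analyzed band), split into half-overlapping Hann frames, and
    the squared real cepstrum of each frame's dB power spectrum (inverse
    transform of the full symmetric spectrum) is averaged over frames and
    lightly smoothed across quefrency.
    """
    dec = max(int(round(sample_rate / work_rate)), 1)
    if dec > 1:
        x = sps.decimate(x, dec, ftype="fir", zero_phase=True)
        sample_rate = sample_rate / dec
    frame = min(frame, 1 << int(np.floor(np.log2(x.size))))
    if frame < 256:
        raise InvalidParameterError("signal too short for cepstral analysis")
    w = np.hanning(frame)
    hop = frame // 2
    acc = np.zeros(frame)
    n_frames = 0
    for start in range(0, x.size - frame + 1, hop):
        seg = x[start : start + frame]
        seg = (seg - seg.mean()) * w
        spec_db = 10.0 * np.log10(np.abs(np.fft.rfft(seg)) ** 2 + 1e-20)
        c = np.fft.irfft(spec_db)
        acc += c * c
        n_frames += 1
    pc = acc / n_frames
    if smooth > 1:
        pc = np.convolve(pc, np.ones(smooth) / smooth, mode="same")
    return 10.0 * np.log10(pc + 1e-20), sample_rate


def _cpp_band(
    ceps_db: np.ndarray, sr: float, f0_search: tuple[float, float]
) -> tuple[np.ndarray, int]:
    q_lo = int(np.ceil(sr / f0_search[1]))
    q_hi = min(int(np.floor(sr / f0_search[0])), ceps_db.size // 2 - 1)
    if q_hi <= q_lo + 4:
        raise InvalidParameterError("signal too short for the quefrency band")
    band = ceps_db[q_lo : q_hi + 1]
    q = np.arange(band.size, dtype=float)
    # trim-refit so a strong peak does not drag the regression baseline
    slope, icpt = np.polyfit(q, band, 1)
    resid = band - (slope * q + icpt)
    keep = resid < np.percentile(resid, 90)
    slope, icpt = np.polyfit(q[keep], band[keep], 1)
    return band - (slope * q + icpt), q_lo


def cpp(
    audio: np.ndarray,
    sample_rate: float,
    f0_search: tuple[float, float] = (60.0, 500.0),
) -> float:
    """Cepstral peak prominence (dB) of the whole signal.

    The frame-averaged power cepstrum (see :func:`_power_cepstrum`) is
    searched in the quefrency band [1/f0_max, 1/f0_min]; a linear
    regression over the band (refit after trimming the top decile of
    deviations) provides the baseline, and CPP is the peak height above
    the regression prediction at the peak quefrency.  Invariant to signal
    amplitude scaling; near zero for aperiodic signals, above ~10 dB for
    healthy periodic phonation.
    """
    x = np.asarray(audio, dtype=float)
    if x.size < 4096:
        raise InvalidParameterError("CPP needs at least 4096 samples")
    ceps_db, sr = _power_cepstrum(x, sample_rate)
    resid, _ = _cpp_band(ceps_db, sr, f0_search)
    return float(resid.max())


def cpp_peak_quefrency(
    audio: np.ndarray,
    sample_rate: float,
    f0_search: tuple[float, float] = (60.0, 500.0),
) -> float:
    """Quefrency (seconds) of the cepstral peak used by :func:`cpp`."""
    x = np.asarray(audio, dtype=float)
    if x.size < 4096:
        raise InvalidParameterError("CPP needs at least 4096 samples")
    ceps_db, sr = _power_cepstrum(x, sample_rate)
    resid, q_lo = _cpp_band(ceps_db, sr, f0_search)
    return (q_lo + int(np.argmax(resid))) / sr


# units and formula identifiers for the self-describing report
_GAW_FIELDS = {
    "mean_jitter_ms": ("ms", "mean|T[i+1]-T[i]|*1000"),
    "jitter_pct": ("au", "100*mean|dT|/mean(T)"),
    "mean_shimmer_db": ("dB", "mean|20*log10(A[i+1]/A[i])|"),
    "shimmer_pct": ("au", "100*mean|dA|/mean(A)"),
    "f0_hz": ("Hz", "1/mean(T)"),
    "open_quotient": ("au", "mean(t_open/T)"),
    "closing_quotient": ("au", "mean(t_closing/t_open)"),
    "speed_quotient": ("au", "mean(t_opening/t_closing)"),
    "asymmetry_quotient": ("au", "mean(t_opening/t_open)"),
    "rate_quotient": ("au", "mean((t_closed+t_opening)/t_closing)"),
    "amplitude_quotient": ("au", "mean(A/|min dA/dt|), dt in frames"),
    "speed_index": ("au", "mean((t_opening-t_closing)/t_open)"),
    "glottal_gap_index": ("au", "mean(a_min/a_max)"),
    "stiffness": ("au", "mean(mean|dA/dt|/A), dt in frames"),
    "amplitude_symmetry_index": ("au", "mean(min(A_L,A_R)/max(A_L,A_R))"),
    "phase_asymmetry_index": ("au", "mean(wrap(|t_L-t_R|/T))"),
    "apf": ("au", "100*mean(|A[i]-A[i+1]|/A[i])"),
    "apq3": ("au", "100*mean|A-mean(3-window)|/mean(A)"),
    "apq5": ("au", "100*mean|A-mean(5-window)|/mean(A)"),
    "apq11": ("au", "100*mean|A-mean(11-window)|/mean(A)"),
}
_AUDIO_FIELDS = {
    "mean_jitter_ms": _GAW_FIELDS["mean_jitter_ms"],
    "jitter_pct": _GAW_FIELDS["jitter_pct"],
    "mean_shimmer_db": _GAW_FIELDS["mean_shimmer_db"],
    "shimmer_pct": _GAW_FIELDS["shimmer_pct"],
    "f0_hz": _GAW_FIELDS["f0_hz"],
    "hnr_db": ("dB", "Yumoto 10*log10(N*sum fbar^2/sum (f_i-fbar)^2)"),
    "cpp_db": ("dB", "cepstral peak minus regression baseline"),
    "apf": _GAW_FIELDS["apf"],
    "apq3": _GAW_FIELDS["apq3"],
    "apq5": _GAW_FIELDS["apq5"],
    "apq11": _GAW_FIELDS["apq11"],
}


@dataclass
class ParameterReport:
    """All GAW-based and audio-based clinical parameters with units.

    Missing components (e.g. no audio) leave their fields ``None`` --
    absent, never silently zero.
    """

    gaw: dict[str, Optional[float]] = field(default_factory=dict)
    audio: dict[str, Optional[float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def rows(self) -> list[dict]:
        """Flatten into CSV-ready rows: name, value, unit, source, formula."""
        out = []
        for source, values, meta in (
            ("GAW", self.gaw, _GAW_FIELDS),
            ("Audio", self.audio, _AUDIO_FIELDS),
        ):
            for name, (unit, formula) in meta.items():
                if name not in values:
                    continue
                out.append(
                    {
                        "name": name,
                        "value": values[name],
                        "unit": unit,
                        "source_signal": source,
                        "formula_id": formula,
                    }
                )
        return out


def compute_report(
    gaw: Optional[GAW] = None,
    cycles: Optional[CycleSet] = None,
    hemi: Optional[HemiGAW] = None,
    audio: Optional[np.ndarray] = None,
    audio_rate: Optional[float] = None,
    audio_cycles: Optional[AudioCycles] = None,
) -> ParameterReport:
    """Assemble every available parameter into one report.

    GAW-side parameters need ``gaw`` + phase-decomposed ``cycles`` (and
    ``hemi`` for the symmetry indices); audio-side parameters need
    ``audio`` + ``audio_rate`` (cycles are detected on demand).  Component
    errors degrade the affected fields to ``None`` with a recorded
    warning instead of failing the whole report.
    """
    report = ParameterReport()

    def tryset(dest: dict, names: Sequence[str], fn) -> None:
        try:
            vals = fn()
        except Exception as exc:  # noqa: BLE001 - degrade per field
            report.warnings.append(f"{'/'.join(names)}: {exc}")
            vals = (None,) * len(names)
        if len(names) == 1:
            vals = (vals,) if not isinstance(vals, tuple) else vals
        for name, v in zip(names, vals):
            dest[name] = v

    if gaw is not None and cycles is not None:
        g = report.gaw
        tryset(g, ["f0_hz"], lambda: fundamental_frequency(cycles))
        tryset(g, ["mean_jitter_ms", "jitter_pct"], lambda: jitter(cycles))
        tryset(g, ["mean_shimmer_db", "shimmer_pct"], lambda: shimmer(cycles))
        try:
            pq = phase_quotients(cycles)
            g.update(pq)
        except Exception as exc:  # noqa: BLE001
            report.warnings.append(f"phase_quotients: {exc}")
            g.update({k: None for k in (
                "open_quotient", "closing_quotient", "speed_quotient",
                "asymmetry_quotient", "rate_quotient", "speed_index")})
        tryset(g, ["glottal_gap_index"], lambda: glottal_gap_index(cycles))
        tryset(g, ["amplitude_quotient"], lambda: amplitude_quotient(gaw, cycles))
        tryset(g, ["stiffness"], lambda: stiffness(gaw, cycles))
        if hemi is not None:
            tryset(
                g,
                ["amplitude_symmetry_index", "phase_asymmetry_index"],
                lambda: symmetry_indices(hemi, cycles),
            )
        try:
            g.update(amplitude_perturbation(cycles))
        except Exception as exc:  # noqa: BLE001
            report.warnings.append(f"amplitude_perturbation(GAW): {exc}")
            g.update({"apf": None, "apq3": None, "apq5": None, "apq11": None})

    if audio is not None and audio_rate is not None:
        a = report.audio
        try:
            ac = audio_cycles or detect_audio_cycles(audio, audio_rate)
        except Exception as exc:  # noqa: BLE001
            report.warnings.append(f"detect_audio_cycles: {exc}")
            ac = None
        if ac is not None:
            tryset(a, ["f0_hz"], lambda: fundamental_frequency(ac))
            tryset(a, ["mean_jitter_ms", "jitter_pct"], lambda: jitter(ac))
            tryset(a, ["mean_shimmer_db", "shimmer_pct"], lambda: shimmer(ac))
            tryset(a, ["hnr_db"], lambda: hnr(audio, ac))
            try:
                a.update(amplitude_perturbation(ac))
            except Exception as exc:  # noqa: BLE001
                report.warnings.append(f"amplitude_perturbation(audio): {exc}")
                a.update({"apf": None, "apq3": None, "apq5": None, "apq11": None})
        tryset(a, ["cpp_db"], lambda: cpp(audio, audio_rate))

    return report
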