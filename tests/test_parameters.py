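"""Clinical parameter formulas: oracle arithmetic, recovery and properties."""

import numpy as np
import pytest

from glottokit.errors import (
    InvalidParameterError,
    TooFewCyclesError,
    UndefinedMeasureError,
)
from glottokit.midline import HemiGAW
from glottokit.parameters import (
    amplitude_perturbation,
    amplitude_quotient,
    compute_report,
    cpp,
    cpp_peak_quefrency,
    detect_audio_cycles,
    fundamental_frequency,
    glottal_gap_index,
    hnr,
    jitter,
    phase_quotients,
    shimmer,
    stiffness,
    symmetry_indices,
)
from glottokit.synthetic import PhonationSpec, render_audio, render_video, synth_gaw_schedule
from glottokit.waveform import GAW, CycleSet, decompose_phases, detect_cycles, gaw_from_masks


class FakeCycles:
    """Minimal periods/amplitudes container for formula oracles."""

    def __init__(self, periods=None, amplitudes=None):
        n = len(periods) if periods is not None else len(amplitudes)
        self._p = np.asarray(periods if periods is not None else [0.01] * n, float)
        self._a = np.asarray(amplitudes if amplitudes is not None else [1.0] * n, float)

    @property
    def periods(self):
        return self._p

    @property
    def amplitudes(self):
        return self._a


class TestF0AndPerturbation:
    def test_f0_is_inverse_mean_period(self):
        assert fundamental_frequency(FakeCycles([0.010] * 30)) == pytest.approx(100.0)
        assert fundamental_frequency(
            FakeCycles([0.009, 0.011] * 15)
        ) == pytest.approx(100.0)
        with pytest.raises(TooFewCyclesError):
            fundamental_frequency(FakeCycles([0.01]))

    def test_jitter_examples(self):
        assert jitter(FakeCycles([0.010] * 10)) == (0.0, 0.0)
        mj, jp = jitter(FakeCycles([0.010, 0.011, 0.010, 0.011]))
        assert mj == pytest.approx(1.0)
        assert jp == pytest.approx(100 * 0.001 / 0.0105, rel=1e-6)

    def test_jitter_of_gaussian_period_perturbation(self):
        # E|T_{i+1}-T_i| for iid N(0, s) perturbations is 2s/sqrt(pi)
        rng = np.random.default_rng(0)
        sigma = 1e-4
        vals = []
        for _ in range(50):
            T = 0.004 + rng.normal(0, sigma, 400)
            vals.append(jitter(FakeCycles(T))[0])
        expected_ms = 2 * sigma / np.sqrt(np.pi) * 1e3
        assert abs(np.mean(vals) - expected_ms) / expected_ms <= 0.15

    def test_shimmer_examples(self):
        assert shimmer(FakeCycles(amplitudes=[2.0] * 8)) == (0.0, 0.0)
        db, _ = shimmer(FakeCycles(amplitudes=[1, 2, 1, 2]))
        assert db == pytest.approx(20 * np.log10(2), rel=1e-9)
        _, pct = shimmer(FakeCycles(amplitudes=[1.0, 1.1]))
        assert pct == pytest.approx(100 * 0.1 / 1.05, rel=1e-6)
        with pytest.raises(InvalidParameterError):
            shimmer(FakeCycles(amplitudes=[1.0, 0.0]))


def cycle_set(t_opening, t_closing, t_closed, fps=1000.0):
    n = len(t_opening)
    T = np.asarray(t_opening) + np.asarray(t_closing) + np.asarray(t_closed)
    frames = np.round(T * fps).astype(int)
    start = np.concatenate(([0], np.cumsum(frames[:-1])))
    cs = CycleSet(
        start=start,
        max_idx=start
        + np.clip(
            np.round(np.asarray(t_opening) * fps).astype(int), 1, frames - 1
        ),
        end=start + frames,
        frame_rate=fps,
        a_min=np.zeros(n),
        a_max=np.ones(n),
    )
    cs.t_opening = np.asarray(t_opening, float)
    cs.t_closing = np.asarray(t_closing, float)
    cs.t_closed = np.asarray(t_closed, float)
    return cs


class TestPhaseQuotients:
    def test_symmetric_cycle_anchors(self):
        # equal opening/closing, no closed phase: CQ 0.5, SI 0 and friends
        cs = cycle_set([0.005] * 10, [0.005] * 10, [0.0] * 10)
        q = phase_quotients(cs)
        assert q["open_quotient"] == pytest.approx(1.0)
        assert q["closing_quotient"] == pytest.approx(0.5)
        assert q["speed_quotient"] == pytest.approx(1.0)
        assert q["asymmetry_quotient"] == pytest.approx(0.5)
        assert q["rate_quotient"] == pytest.approx(1.0)
        assert q["speed_index"] == pytest.approx(0.0)

    def test_three_to_one_cycle(self):
        cs = cycle_set([3.0], [1.0], [0.0], fps=1.0)
        q = phase_quotients(cs)
        assert q["speed_quotient"] == pytest.approx(3.0)
        assert q["speed_index"] == pytest.approx(0.5)
        assert q["asymmetry_quotient"] == pytest.approx(0.75)
        assert q["closing_quotient"] == pytest.approx(0.25)
        assert q["rate_quotient"] == pytest.approx(3.0)

    def test_time_reversal_flips_si_and_inverts_sq(self):
        fwd = phase_quotients(cycle_set([3.0], [1.0], [1.0], fps=1.0))
        rev = phase_quotients(cycle_set([1.0], [3.0], [1.0], fps=1.0))
        assert rev["speed_index"] == pytest.approx(-fwd["speed_index"])
        assert rev["speed_quotient"] == pytest.approx(1 / fwd["speed_quotient"])

    def test_zero_closing_cycles_excluded_with_warning(self):
        cs = cycle_set([0.004, 0.005], [0.0, 0.005], [0.0, 0.0])
        with pytest.warns(UserWarning, match="zero closing"):
            q = phase_quotients(cs)
        assert q["closing_quotient"] == pytest.approx(0.5)


class TestAreaMeasures:
    def test_glottal_gap_index(self):
        cs = cycle_set([0.005] * 4, [0.005] * 4, [0.0] * 4)
        cs.a_min = np.zeros(4)
        assert glottal_gap_index(cs) == 0.0
        cs.a_min = np.full(4, 0.15)
        assert glottal_gap_index(cs) == pytest.approx(0.15)

    def test_amplitude_quotient_triangle(self):
        # rise 3 frames to 9 px, fall 3 frames: steepest decline 3 px/frame
        a = np.array([0, 3, 6, 9, 6, 3, 0, 3, 6, 9, 6, 3, 0, 3, 6, 9, 6, 3, 0], float)
        g = GAW(a, 4000.0)
        cs = detect_cycles(g)
        assert amplitude_quotient(g, cs) == pytest.approx(3.0)
        g2 = GAW(a * 7.5, 4000.0)
        assert amplitude_quotient(g2, detect_cycles(g2)) == pytest.approx(3.0)

    def test_amplitude_quotient_sine_closed_form(self):
        # raised sinusoid with N frames/cycle: |min derivative| = A*pi/N
        N = 40
        k = np.arange(N * 12)
        a = 1 - np.cos(2 * np.pi * k / N)
        g = GAW(a, 4000.0)
        got = amplitude_quotient(g, detect_cycles(g))
        assert got == pytest.approx(N / np.pi, rel=0.05)

    def test_stiffness_triangle_and_scale_invariance(self):
        a = np.array([0, 2, 4, 2, 0, 2, 4, 2, 0, 2, 4, 2, 0], float)
        g = GAW(a, 4000.0)
        assert stiffness(g, detect_cycles(g)) == pytest.approx(0.5)
        g2 = GAW(a * 123.0, 4000.0)
        assert stiffness(g2, detect_cycles(g2)) == pytest.approx(0.5)

    def test_stiffness_follows_total_variation_law(
        self, healthy_spec, healthy_schedule, healthy_masks
    ):
        # any unimodal cycle has mean |da| = 2A/N, hence stiffness = 2/N
        gaw = gaw_from_masks(healthy_masks)
        cycles = detect_cycles(gaw)
        N = healthy_spec.fps / healthy_spec.f0
        assert stiffness(gaw, cycles) == pytest.approx(2 / N, rel=0.10)


class TestSymmetryIndices:
    def make_hemi(self, ratio=1.0, lag_frames=0.0, n_cycles=10, N=40):
        k = np.arange(n_cycles * N)
        right = 1 - np.cos(2 * np.pi * k / N)
        left = ratio * (1 - np.cos(2 * np.pi * (k - lag_frames) / N))
        hemi = HemiGAW(left, right, 4000.0)
        g = GAW(left + right, 4000.0)
        return hemi, detect_cycles(g)

    def test_identical_sides(self):
        hemi, cs = self.make_hemi()
        asi, pai = symmetry_indices(hemi, cs)
        assert asi == pytest.approx(1.0)
        assert pai == pytest.approx(0.0, abs=1e-6)

    def test_amplitude_ratio(self):
        hemi, cs = self.make_hemi(ratio=0.9)
        asi, pai = symmetry_indices(hemi, cs)
        assert asi == pytest.approx(0.9, abs=1e-6)
        assert pai == pytest.approx(0.0, abs=1e-6)

    def test_quarter_period_delay(self):
        hemi, cs = self.make_hemi(lag_frames=10.0)  # T/4 at N = 40
        _, pai = symmetry_indices(hemi, cs)
        assert pai == pytest.approx(0.25, abs=0.02)

    def test_zero_amplitude_side_raises(self):
        hemi = HemiGAW(np.zeros(80), 1 - np.cos(2 * np.pi * np.arange(80) / 40))
        g = GAW(hemi.total, 4000.0)
        with pytest.raises(UndefinedMeasureError):
            symmetry_indices(hemi, detect_cycles(g))


def apq_bruteforce(A, k):
    """Independent oracle: centered k-window amplitude perturbation quotient."""
    A = np.asarray(A, float)
    half = k // 2
    devs = [
        abs(A[i] - A[i - half : i + half + 1].mean())
        for i in range(half, A.size - half)
    ]
    return 100.0 * np.mean(devs) / A.mean()


class TestAmplitudePerturbation:
    def test_constant_amplitudes_are_zero(self):
        out = amplitude_perturbation(FakeCycles(amplitudes=[2.0] * 15))
        assert out["apf"] == 0.0
        assert out["apq3"] == out["apq5"] == out["apq11"] == 0.0

    def test_alternating_sequence_matches_bruteforce(self):
        A = [1.0, 2.0] * 8
        out = amplitude_perturbation(FakeCycles(amplitudes=A))
        for k in (3, 5, 11):
            assert out[f"apq{k}"] == pytest.approx(apq_bruteforce(A, k))
        # frozen from the oracle: centered 3-window on 1,2,1,2,...
        assert out["apq3"] == pytest.approx(44.4444, abs=1e-3)

    def test_single_outlier_ordering_matches_bruteforce(self):
        A = [1.0] * 6 + [2.0] + [1.0] * 6
        out = amplitude_perturbation(FakeCycles(amplitudes=A))
        brute = {k: apq_bruteforce(A, k) for k in (3, 5, 11)}
        for k in (3, 5, 11):
            assert out[f"apq{k}"] == pytest.approx(brute[k])
        # wider centered windows integrate more of an isolated outlier
        assert brute[3] < brute[5] < brute[11]

    def test_apf_formula(self):
        out = amplitude_perturbation(FakeCycles(amplitudes=[1.0, 1.5, 1.0]))
        assert out["apf"] == pytest.approx(100 * (0.5 / 1.0 + 0.5 / 1.5) / 2)

    def test_window_larger_than_series_reports_missing(self):
        out = amplitude_perturbation(FakeCycles(amplitudes=[1.0, 1.1, 1.2]))
        assert out["apq11"] is None
        assert out["apq3"] is not None


def periodic_pulse(n_cycles=60, N=320, sr=80_000.0):
    """Smooth periodic waveform with one pulse per cycle."""
    k = np.arange(n_cycles * N)
    ph = (k % N) / N
    x = np.where(ph < 0.5, np.sin(np.pi * ph / 0.5) ** 2, 0.0)
    return x, sr


class TestHNR:
    def test_known_snr_recovered(self):
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(10):
            x, sr = periodic_pulse()
            rms = np.sqrt(np.mean(x**2))
            noisy = x + rng.normal(0, rms * 10 ** (-15 / 20), x.size)
            ac = detect_audio_cycles(noisy, sr)
            errs.append(hnr(noisy, ac) - 15.0)
        assert abs(np.median(errs)) <= 1.5

    def test_perfectly_periodic_capped(self):
        x, sr = periodic_pulse()
        ac = detect_audio_cycles(x, sr)
        assert hnr(x, ac) == 120.0

    def test_equal_energy_noise_near_zero_db(self):
        rng = np.random.default_rng(2)
        x, sr = periodic_pulse()
        rms = np.sqrt(np.mean(x**2))
        noisy = x + rng.normal(0, rms, x.size)
        ac = detect_audio_cycles(noisy, sr)
        assert abs(hnr(noisy, ac)) <= 2.0

    def test_silent_signal_raises(self):
        with pytest.raises(UndefinedMeasureError):
            detect_audio_cycles(np.zeros(80_000), 80_000.0)


class TestCPP:
    def test_white_noise_has_no_cepstral_peak(self):
        rng = np.random.default_rng(3)
        vals = [cpp(rng.normal(0, 1, 40_000), 80_000.0) for _ in range(10)]
        assert max(vals) < 5.0

    def test_periodic_voice_peak_location_and_height(self):
        spec = PhonationSpec(seed=7, duration=0.5)
        schedule = synth_gaw_schedule(spec)
        rec, truth = render_audio(spec, schedule)
        x = rec.audio[: truth["n_voice_samples"]]
        assert cpp(x, rec.sample_rate) > 10.0
        q = cpp_peak_quefrency(x, rec.sample_rate)
        assert abs(q - 1 / spec.f0) / (1 / spec.f0) <= 0.05

    def test_amplitude_invariance(self):
        spec = PhonationSpec(seed=8, duration=0.4)
        rec, truth = render_audio(spec, synth_gaw_schedule(spec))
        x = rec.audio[: truth["n_voice_samples"]]
        assert cpp(2 * x, rec.sample_rate) == pytest.approx(
            cpp(x, rec.sample_rate), abs=1e-9
        )

    def test_short_signal_rejected(self):
        with pytest.raises(InvalidParameterError):
            cpp(np.random.default_rng(0).normal(size=1000), 80_000.0)


class TestComputeReport:
    def test_full_synthetic_recording_populates_all_fields(
        self, healthy_spec, healthy_masks, healthy_recording
    ):
        rec, truth = healthy_recording
        gaw = gaw_from_masks(healthy_masks)
        cycles = decompose_phases(gaw, detect_cycles(gaw))
        from glottokit.midline import estimate_midline, split_hemi_gaw

        midlines = estimate_midline(healthy_masks, cycles)
        hemi = split_hemi_gaw(healthy_masks, midlines)
        report = compute_report(
            gaw=gaw, cycles=cycles, hemi=hemi,
            audio=rec.audio[: truth["n_voice_samples"]],
            audio_rate=rec.sample_rate,
        )
        assert len(report.gaw) == 20
        assert len(report.audio) == 11
        assert all(v is not None for v in report.gaw.values())
        assert all(v is not None for v in report.audio.values())
        rows = report.rows()
        assert len(rows) == 31
        assert {r["source_signal"] for r in rows} == {"GAW", "Audio"}

    def test_video_only_report_has_no_audio_fields(self, healthy_masks):
        gaw = gaw_from_masks(healthy_masks)
        cycles = decompose_phases(gaw, detect_cycles(gaw))
        report = compute_report(gaw=gaw, cycles=cycles)
        assert report.audio == {}
        assert report.gaw["f0_hz"] is not None

    def test_audio_only_report_has_no_gaw_fields(self, healthy_recording):
        rec, truth = healthy_recording
        report = compute_report(
            audio=rec.audio[: truth["n_voice_samples"]], audio_rate=rec.sample_rate
        )
        assert report.gaw == {}
        assert report.audio["f0_hz"] is not None


class TestHealthyBandPlausibility:
    def test_default_phonation_lands_in_published_healthy_ranges(
        self, healthy_masks
    ):
        """Phase quotients of the default phonation fall inside the
        min-max envelopes reported for normophonic sustained phonation."""
        gaw = gaw_from_masks(healthy_masks)
        cycles = decompose_phases(gaw, detect_cycles(gaw))
        q = phase_quotients(cycles)
        bands = {
            "open_quotient": (0.989, 1.000),
            "closing_quotient": (0.402, 0.567),
            "speed_quotient": (0.971, 1.093),
            "asymmetry_quotient": (0.482, 0.518),
            "rate_quotient": (0.973, 1.129),
            "speed_index": (-0.035, 0.035),
        }
        for name, (lo, hi) in bands.items():
            assert lo <= q[name] <= hi, name
        from glottokit.midline import estimate_midline, split_hemi_gaw

        midlines = estimate_midline(healthy_masks, cycles)
        hemi = split_hemi_gaw(healthy_masks, midlines)
        asi, pai = symmetry_indices(hemi, cycles)
        assert 0.932 <= asi <= 0.993
        assert 0.006 <= pai <= 0.258
        assert 0.0 <= glottal_gap_index(cycles) <= 0.367
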