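# Methods

This note documents the models, conventions and numerical choices behind
`glottokit`, and what the synthetic validation does and does not show.

## Signal model and coordinate conventions

A recording couples three signals: video frames at rate `fps` (default
4000), a microphone channel and a camera reference channel, both at
`sample_rate` (default 80 kHz). The reference channel carries one short
pulse per recorded frame and goes quiet after the external stop trigger,
while the audio interface records roughly one further second.

All image geometry uses 0-based pixel coordinates, x right, y down. By
default the image-top extreme of the glottis is taken as the posterior
commissure (the typical orientation of a 70° rigid endoscope held upright)
and "left"/"right" mean image-left/image-right; the anatomical
left–right mapping depends on endoscope handling and is deliberately not
assumed. Both conventions are configurable and stamped into the output
metadata.

## Audio–video alignment

The reference channel is reduced to a rolling standard deviation over a
2.5 ms centered window (shrunken at the edges; the signal is mean-centered
first so a constant input is exactly zero). The trace is z-scored and the
end trigger is the most prominent peak of the window-lagged falling
difference `z[i] − z[i+w]`: a pulsed→quiescent step becomes a clean
triangular peak of height equal to the full step, while train onsets
(rising steps) are ignored. If no peak reaches prominence 1, the last
sample whose rolling std exceeds half its robust maximum is used. A
candidate is accepted only if the tail after it is genuinely quiescent
(tail rolling-std mean below 25% of the pre-trigger mean); flat or fully
pulsed references therefore raise a trigger-not-found error. A plain
"last z > 1 sample" rule was rejected: for a step signature the in-train
z value is `sqrt(tail/train)`, which is below 1 whenever the pulse train
outlasts the quiescent tail.

Frame pulses are peaks of the raw reference up to the trigger, with
minimum spacing half the nominal frame interval and height 50% of the
99th-percentile pre-trigger amplitude; polarity is auto-detected, and the
search signal is padded at both ends so pulses at the very first or last
sample are not lost. The measured median spacing is compared with
`sample_rate/fps`; a >2% disagreement warns about wrong fps metadata.

## Segmentation

The classical baseline inverts intensity, applies a global Otsu
threshold, labels connected components and keeps the one overlapping the
frame-center region most — then intersects it with a darkness cut
(pixels at least 60 8-bit counts below the frame median) and keeps the
largest remaining component. The darkness margin sits between the
tissue-texture spread and the glottis intensity; without it, Otsu
degenerates on frames where the glottis is nearly closed and a tiny dark
object no longer dominates the histogram. Degenerate frames yield empty
masks, never errors. The model path accepts any callable mapping one
frame to a per-pixel probability map; maps are thresholded at 0.5 and
post-filtered to the largest component (both configurable).

## Cycles and phases

Cycles are delimited minimum-to-minimum around GAW maxima found with a
prominence of 10% of the signal range. On a flat closed-phase plateau the
boundary is placed at the plateau middle, which keeps period estimates
unbiased instead of assigning the whole closed phase to one neighbor. A
signal endpoint counts as a boundary only when its value is down at the
interior-minima level (within 5% of the range), so a recording cut at
closure keeps its first/last cycle while mid-cycle truncations are
discarded.

A frame is *open* when its area exceeds `θ_i = ε·a_max,i` (default
ε = 0.02). The threshold is relative to the cycle peak, not offset by the
cycle minimum: closure means the glottal area is physically near zero, so
a waveform whose floor stays above θ never closes (`t_closed = 0`,
OQ = 1) — the regime typical of healthy phonation, where posterior gaps
keep the measured OQ at ~1.0. Phase timing uses the threshold crossings
at whole-frame resolution: opening runs from the last closed frame before
the first open frame (or the cycle start) to the maximum, closing from
the maximum to the first closed frame after the last open frame (or the
cycle end). Sub-frame interpolation of event times is deliberately out of
scope; the cost is a systematic `+2 frames/cycle` widening of the open
phase in deep-closure regimes (≈ 2/N in OQ for N frames per cycle),
negligible when the glottis never fully closes.

Amplitudes are offset-free (`A_i = a_max − a_min`) so perturbation
measures do not depend on a segmentation offset.

## Midline, hemi-GAWs, PVG

At each cycle maximum the masks of the surrounding ±2 frames are summed
and the midline is the line through the weighted centroid along the
principal axis (image moments `½·atan2(2μ11, μ20−μ02)` or the dominant
eigenvector of the coordinate covariance — both available, they agree on
elongated masks). Near-circular masks (eigenvalue ratio > 0.95) are
flagged degenerate. Commissure points are the extreme projections of mask
pixels onto the axis, dropped back onto the line. Intermediate frames use
the temporally nearest anchor estimate (linear interpolation would
smooth, but nearest is simplest and testable).

Hemi-areas classify each mask pixel by the sign of its perpendicular
distance to the midline; pixels within half a pixel of the line split
half/half, so left + right equals the total GAW exactly. Note one known
bias: with asymmetric folds the area centroid — and hence the midline —
shifts toward the wider fold, pulling the measured amplitude-symmetry
index toward 1. At realistic glottis widths (≥ ~10 px) the bias is below
0.03; on very thin glottides it grows.

The phonovibrogram samples M = 64 equidistant stations between posterior
and anterior points; each station row holds the maximum perpendicular
distance of mask pixels within ±half a station spacing, per side. Left
fold rows run posterior→anterior from the top; right fold rows are
mirrored below so the anterior ends meet at the horizontal center. Raw
pixel distances are kept (no per-recording normalization); the PNG export
scales to 16 bit and records the scale.

## Audio cycle analysis, HNR, CPP

An autocorrelation F0 prior (parabolic-refined peak in the 60–500 Hz lag
range) gates cycle detection: the signal is low-pass filtered at 4·F0
(zero-phase Butterworth), peaks are picked with minimum spacing 0.6
periods, and peak instants are parabolic-interpolated for sub-sample
period resolution. A narrow 0.5–1.5·F0 band-pass was rejected for the
measurement step: its ringing spans neighboring cycles and attenuates
genuine cycle-to-cycle perturbation. Per-cycle amplitudes are measured
peak-to-following-trough on the filtered signal.

HNR follows the ensemble method: every cycle is resampled to the mean
cycle length, and the ratio of the mean-waveform energy to the
cycle-to-cycle residual energy is reported in dB, capped at 120 dB for a
zero residual.

CPP uses the frame-averaged power cepstrum: the signal is decimated to a
10 kHz working rate (cepstral voice analysis convention — the harmonic
comb must occupy a substantial fraction of the analyzed band), cut into
1024-point Hann frames with half overlap, and the squared real cepstrum
of each frame's dB power spectrum (inverse transform of the full
symmetric spectrum) is averaged over all frames of the complete signal
and lightly smoothed across quefrency (5 bins). The peak is taken in the
quefrency band [1/500 s, 1/60 s] relative to a linear baseline fitted to
the band and refitted after trimming the top decile of deviations (so
the peak itself does not drag the baseline). A single whole-signal FFT
was rejected: with minutes-scale frequency resolution the rahmonic is
diluted to under 1 dB even for perfectly periodic voice. The implemented
recipe yields ~15–25 dB for clean synthetic phonation and ~2–4 dB for
white noise, matching the >10 dB healthy-voice convention.

## NIQE

MSCN coefficients use a 7×7 Gaussian window (σ = 7/6) on the 8-bit
intensity scale with the +1 stabilizer. Features are the standard 18 per
scale (GGD shape/variance of MSCN, AGGD shape/mean/left/right variance of
the four neighbor products) over non-overlapping 96 px patches at two
scales (the patch shrinks with the image so features describe the same
region), 36 dimensions total. The score is
`sqrt(dᵀ((Σ_model+Σ_test)/2)⁻¹ d)`; a singular pooled covariance falls
back to a pseudo-inverse with a warning.

No published reference model file is shipped. `fit_niqe_model` fits the
reference to any user-provided pristine folder; `default_model` builds a
deterministic synthetic reference from seeded images labelled as such:
fractal (multi-octave, `σ^0.7` amplitude law) textures — textured at
every scale with no single-pixel noise component, like natural scenes —
with a few dark high-contrast elliptical regions (the statistics of dark
openings on bright tissue) and mild point-spread/contrast diversity.
Because NIQE scores are model-relative, every score is reported with its
model provenance, and the shipped checks are relative ones: zero
self-distance at the model mean, and strictly increasing scores under
progressive blur (σ = 0,1,2,4) and noise (σ = 1,2,4 counts) on clean
synthetic endoscopy frames. Beyond σ ≈ 4 counts of noise the distance
saturates and single-realization variance dominates, so ordering between
*heavy* distortion levels is not guaranteed (clean-versus-heavy remains
strictly ordered).

## Synthetic study conditions

The generator emulates a healthy sustained phonation by default: F0
250 Hz, 0.25 s of video (1000 frames — a standard analysis segment
length) at 4000 fps, 80 kHz audio, glottal floor 0.15 of the peak area
(so OQ = 1.0 and GGI ≈ 0.15), symmetric cycles (SI = 0, CQ = 0.5),
left/right amplitude ratio 0.97 and phase lag 0.02 of a period, jitter
σ = 70 µs, shimmer σ = 2%, audio SNR 40 dB, pixel noise σ = 5 counts.
These sit at the centers of published normophonic ranges; the per-cycle
template is a skewed raised sinusoid whose peak position encodes the
speed-index target and whose open fraction encodes the open-quotient
target.

The attached ground-truth targets are evaluated analytically on a fine
phase grid of the *constructed* waveform, not echoed from the spec
fields: with a phase lag the summed left+right area genuinely has a
higher minimum and a shifted peak than either fold's template.

Rendering draws a dark lens (two opposed parabolic edges about the
midline, displacement zero at the commissures) on bright tissue with
multi-scale mucosa-like texture, band-limits the frame with an
optics-like point-spread blur (σ = 0.5 px) and adds pixel noise; the
returned masks are the exact rasterization. The voice channel is a
Rosenberg-type glottal flow pulse with *fixed open time* (period
perturbation stretches the closed phase, as for a source whose open time
is set by fold mechanics) plus a broadband excitation at each glottal
closure — the dominant acoustic event — which supplies the full harmonic
comb a real voice carries. The reference channel carries 3-sample pulses
every `sample_rate/fps` samples, ceasing at the trigger, followed by one
second of silence. No vocal-tract filter is applied and no acoustic
propagation delay is modelled.

What passing tests show — and what they do not: the synthetic scenes have
ideal contrast, a single glottal gap, no camera motion, no specular
highlights and no mucus bridges; the classical segmenter's accuracy on
them does not transfer to clinical footage (that is what trained
segmentation models are for — the pipeline accepts them as drop-in
handles). The acoustic model validates cycle-based and spectral measures,
not formant-dependent ones.

## Problem sizes and tolerances

The shipped validation uses 0.25 s recordings (≈ 25–100 cycles) at
128–256 px, 20 seeds per property: audio-vs-video F0 agreement (median
≤ 2 Hz; measured ≈ 0.1 Hz), trigger recovery within one rolling-std
window (±200 samples), exact frame counts, phase-quotient anchors on
symmetric cycles (CQ = 0.5, SI = 0 to within one-frame quantization),
recovery of injected OQ/SI/GGI/ASI/PAI within ±0.05 and of injected
jitter/shimmer within 20% relative (measured ≈ 5%), exact hemi-GAW/total
conservation, and exact zeros of all perturbation measures on perfectly
periodic input (video side exact; audio side to the ~1e-3 floating-point
floor of the filtering chain).

## Known limitations

- Whole-frame event timing biases OQ upward by ≈ 2/N in deep-closure
  regimes (see above).
- Stiffness, defined as mean |Δa| per frame over the cycle amplitude, is
  exactly 2/N for any unimodal sampled cycle (total-variation identity) —
  on smooth synthetic cycles it measures frames-per-cycle, not tissue
  property; clinically reported values reflect real GAW shape and noise.
- The centroid-based midline drifts toward the wider fold on strongly
  asymmetric, very thin glottides.
- mp4 IO requires an ffmpeg-backed imageio plugin; lossless frame
  directories are the validated path.
- NIQE absolute values depend on the reference model and are not
  comparable across models.
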