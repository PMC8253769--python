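"""Shared fixtures: one default healthy phonation, rendered once per session."""

import numpy as np
import pytest

from glottokit.synthetic import (
    PhonationSpec,
    render_audio,
    render_video,
    synth_gaw_schedule,
)


@pytest.fixture(scope="session")
def healthy_spec():
    return PhonationSpec(seed=42)


@pytest.fixture(scope="session")
def healthy_schedule(healthy_spec):
    return synth_gaw_schedule(healthy_spec)


@pytest.fixture(scope="session")
def healthy_masks(healthy_spec, healthy_schedule):
    """Ground-truth segmentation of the default healthy phonation."""
    _, seg = render_video(healthy_spec, healthy_schedule, masks_only=True)
    return seg


@pytest.fixture(scope="session")
def healthy_recording(healthy_spec, healthy_schedule):
    return render_audio(healthy_spec, healthy_schedule)


def make_reference(
    n_frames=1000,
    fps=4000.0,
    sample_rate=80_000.0,
    tail_s=1.0,
    pulse=0.9,
    noise=0.0,
    rng=None,
):
    """Bare reference-channel pulse train for sync tests."""
    spf = sample_rate / fps
    n = int(round(n_frames * spf + tail_s * sample_rate))
    ref = np.zeros(n)
    if noise and rng is not None:
        ref += rng.normal(0, noise, n)
    pulses = np.round(np.arange(n_frames) * spf).astype(int)
    for off in range(3):
        ref[pulses + off] += pulse
    return ref, pulses


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
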