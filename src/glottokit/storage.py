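"""Readers/writers for on-disk recording bundles and the pipeline driver.

A recording bundle mirrors the acquisition conventions of clinical
high-speed systems: video as mp4 (h264) or a lossless frame directory,
audio as uncompressed WAV (channel 0 microphone, channel 1 camera
reference), metadata as JSON, glottis segmentations as HDF5 (dataset
``segmentation``, N x H x W uint8), quantitative parameters as CSV and
the phonovibrogram as 16-bit PNG plus HDF5 dataset ``pvg``.

All geometry is serialized in 0-based pixel coordinates, x right,
y down; the orientation conventions (posterior = image top, left/right in
image coordinates) are stamped into the metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import midline as midline_mod
from . import parameters as params_mod
from . import pvg as pvg_mod
from . import sync as sync_mod
from . import waveform as waveform_mod
from .errors import BundleIOError, GlottokitError, TooFewCyclesError
from .segmentation import (
    SegmentationSequence,
    VideoFrames,
    apply_roi,
    segment_model,
    segment_threshold,
)

log = logging.getLogger(__name__)

METADATA_SCHEMA = "glottokit-metadata-1"
_CONVENTIONS = {
    "coordinates": "0-based pixel coordinates, x right, y down",
    "posterior": "image top",
    "left_right": "image coordinates (anatomical mapping not assumed)",
    "pvg_layout": "rows 0..M-1 left fold posterior->anterior; "
    "rows M..2M-1 right fold anterior->posterior",
}

__all__ = [
    "RecordingBundle",
    "PipelineConfig",
    "read_wav",
    "write_wav",
    "read_video",
    "write_frames",
    "read_masks",
    "write_masks",
    "write_pvg",
    "read_metadata",
    "write_metadata",
    "read_bundle",
    "write_bundle",
    "run_pipeline",
]


def read_wav(
    path: str | Path, mic_channel: int = 0, ref_channel: int = 1
) -> sync_mod.TwoChannelRecording:
    """Read a 2-channel PCM WAV into a normalized recording.

    Integer PCM (any depth the container supports, incl. 24-bit stored in
    32-bit frames) is scaled to [-1, 1]; float data passes through.
    """
    path = Path(path)
    if not path.exists():
        raise BundleIOError(f"audio file not found: {path}")
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise BundleIOError(f"{path} is not a 2-channel WAV")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
        bit_depth = np.iinfo(np.int32).bits if scale > 2**16 else 16
    else:
        data = data.astype(float)
        bit_depth = 32
    return sync_mod.TwoChannelRecording(
        audio=data[:, mic_channel],
        reference=data[:, ref_channel],
        sample_rate=float(rate),
        bit_depth=bit_depth,
    )


def write_wav(
    path: str | Path, recording: sync_mod.TwoChannelRecording, dtype: str = "float32"
) -> Path:
    """Write the two channels back to WAV (float32 or 16-bit PCM)."""
    path = Path(path)
    stacked = np.stack([recording.audio, recording.reference], axis=1)
    if dtype == "int16":
        stacked = np.clip(stacked, -1, 1)
        wavfile.write(path, int(recording.sample_rate),
                      (stacked * 32767).astype(np.int16))
    else:
        wavfile.write(path, int(recording.sample_rate), stacked.astype(np.float32))
    return path


_FRAME_EXTS = (".png", ".tif", ".tiff", ".bmp")


def read_video(path: str | Path, frame_rate: float = 4000.0) -> VideoFrames:
    """Read video from an mp4 file or a lossless frame directory.

    A directory is read as its sorted image files (PNG/TIFF); mp4 needs
    an ffmpeg-capable imageio plugin and raises a descriptive error when
    none is importable.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise BundleIOError(f"no frame images found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
        return VideoFrames(frames, frame_rate)
    if not path.exists():
        raise BundleIOError(f"video not found: {path}")
    try:
        frames = iio.imread(path, plugin="pyav")
    except Exception as exc:  # noqa: BLE001
        raise BundleIOError(
            f"cannot decode {path}: mp4/h264 reading requires an "
            f"ffmpeg-capable imageio plugin ({exc})"
        ) from exc
    return VideoFrames(np.asarray(frames), frame_rate)


def write_frames(directory: str | Path, video: VideoFrames) -> Path:
    """Write a frame stack as zero-padded PNGs (lossless round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(video.n_frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", video.frames[i])
    return directory


def write_masks(path: str | Path, seg: SegmentationSequence) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(
            "segmentation", data=seg.masks.astype(np.uint8), compression="gzip"
        )
        ds.attrs["frame_rate"] = seg.frame_rate
        ds.attrs["roi"] = seg.roi if seg.roi is not None else (-1, -1, -1, -1)
    return path


def read_masks(path: str | Path) -> SegmentationSequence:
    path = Path(path)
    if not path.exists():
        raise BundleIOError(f"segmentation file not found: {path}")
    with h5py.File(path, "r") as f:
        if "segmentation" not in f:
            raise BundleIOError(f"{path} lacks the 'segmentation' dataset")
        ds = f["segmentation"]
        roi = tuple(int(v) for v in ds.attrs.get("roi", (-1,) * 4))
        return SegmentationSequence(
            masks=ds[...],
            frame_rate=float(ds.attrs.get("frame_rate", 4000.0)),
            roi=None if roi[0] < 0 else roi,
        )


def write_pvg(
    png_path: str | Path, h5_path: str | Path, pvg: "pvg_mod.Phonovibrogram"
) -> tuple[Path, Path]:
    """PVG as scaled 16-bit PNG (scale recorded in the HDF5/metadata)."""
    png_path, h5_path = Path(png_path), Path(h5_path)
    vmax = pvg.matrix.max()
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    iio.imwrite(png_path, np.round(pvg.matrix * scale).astype(np.uint16))
    with h5py.File(h5_path, "a") as f:
        if "pvg" in f:
            del f["pvg"]
        ds = f.create_dataset("pvg", data=pvg.matrix, compression="gzip")
        ds.attrs["png_scale"] = scale
        for k, v in pvg.metadata.items():
            ds.attrs[k] = v
    return png_path, h5_path


def read_metadata(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise BundleIOError(f"metadata file not found: {path}")
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleIOError(f"corrupt metadata JSON {path}: {exc}") from exc
    for key in ("frame_rate", "sample_rate"):
        if key not in meta:
            raise BundleIOError(f"metadata {path} is missing '{key}'")
    return meta


def write_metadata(path: str | Path, meta: dict) -> Path:
    path = Path(path)
    meta = dict(meta)
    meta.setdefault("schema", METADATA_SCHEMA)
    meta.setdefault("conventions", _CONVENTIONS)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


@dataclass
class RecordingBundle:
    """One recording with its derived products (filled by the pipeline)."""

    video: Optional[VideoFrames] = None
    recording: Optional[sync_mod.TwoChannelRecording] = None
    metadata: dict = field(default_factory=dict)
    segmentation: Optional[SegmentationSequence] = None
    gaw: Optional[waveform_mod.GAW] = None
    cycles: Optional[waveform_mod.CycleSet] = None
    midlines: Optional[list] = None
    hemi: Optional[midline_mod.HemiGAW] = None
    pvg: Optional["pvg_mod.Phonovibrogram"] = None
    alignment: Optional[sync_mod.AlignmentResult] = None
    audio_segment: Optional[np.ndarray] = None
    report: Optional[params_mod.ParameterReport] = None


def read_bundle(
    video_path: Optional[str | Path] = None,
    audio_path: Optional[str | Path] = None,
    metadata_path: Optional[str | Path] = None,
    masks_path: Optional[str | Path] = None,
) -> RecordingBundle:
    """Load bundle members from disk; every member is optional."""
    meta = read_metadata(metadata_path) if metadata_path else {}
    fps = float(meta.get("frame_rate", 4000.0))
    bundle = RecordingBundle(metadata=meta)
    if video_path:
        bundle.video = read_video(video_path, fps)
        sel = meta.get("selected_frames")
        if sel and not (0 <= sel[0] <= sel[1] < bundle.video.n_frames):
            raise BundleIOError(
                f"selected_frames {sel} outside video of "
                f"{bundle.video.n_frames} frames"
            )
    if audio_path:
        bundle.recording = read_wav(audio_path)
        if meta and abs(bundle.recording.sample_rate - meta["sample_rate"]) > 1e-6:
            raise BundleIOError(
                "metadata sample_rate disagrees with the WAV header"
            )
    if masks_path:
        bundle.segmentation = read_masks(masks_path)
    return bundle


def write_bundle(bundle: RecordingBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every present member; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if bundle.video is not None:
        paths["frames"] = write_frames(out / "frames", bundle.video)
    if bundle.recording is not None:
        paths["audio"] = write_wav(out / "audio.wav", bundle.recording)
    if bundle.segmentation is not None:
        paths["masks"] = write_masks(out / "segmentation.hdf5", bundle.segmentation)
    if bundle.pvg is not None:
        png, h5 = write_pvg(out / "pvg.png", out / "segmentation.hdf5", bundle.pvg)
        paths["pvg_png"], paths["pvg_h5"] = png, h5
    if bundle.gaw is not None:
        df = pd.DataFrame(
            {
                "frame": np.arange(bundle.gaw.area.size),
                "time_s": bundle.gaw.time,
                "gaw_px": bundle.gaw.area,
            }
        )
        if bundle.hemi is not None:
            df["left_px"] = bundle.hemi.left_area
            df["right_px"] = bundle.hemi.right_area
        df.to_csv(out / "gaw.csv", index=False)
        paths["gaw"] = out / "gaw.csv"
    if bundle.report is not None:
        pd.DataFrame(bundle.report.rows()).to_csv(out / "parameters.csv", index=False)
        paths["parameters"] = out / "parameters.csv"
    meta = dict(bundle.metadata)
    if bundle.alignment is not None:
        meta["alignment"] = bundle.alignment.to_dict()
    if bundle.midlines is not None:
        meta["midlines"] = [m.to_dict() for m in bundle.midlines]
    paths["metadata"] = write_metadata(out / "metadata.json", meta)
    return paths


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis pipeline."""

    roi: Optional[tuple[int, int, int, int]] = None
    frames: Optional[tuple[int, int]] = None  # selected range, inclusive
    model: Optional[object] = None            # segmentation-model handle
    closure_eps: float = 0.02
    min_prominence_frac: float = 0.1
    midline_method: str = "moments"
    context_frames: int = 2
    pvg_stations: int = 64
    min_cycles: int = 20
    force: bool = False


def _stage(name: str):
    def wrap(fn):
        try:
            log.info("pipeline stage: %s", name)
            return fn()
        except GlottokitError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    return wrap


def run_pipeline(bundle: RecordingBundle, config: PipelineConfig | None = None) -> RecordingBundle:
    """Run sync -> roi/segment -> GAW/cycles -> midline/hemi -> PVG -> parameters.

    Parameters are refused when fewer than ``min_cycles`` (default 20,
    the recommended minimum for stable cycle statistics) complete cycles
    are detected, unless ``config.force`` is set.  Missing audio degrades
    to a GAW-only report with a logged warning.
    """
    cfg = config or PipelineConfig()
    if bundle.video is None and bundle.segmentation is None:
        raise BundleIOError("bundle has neither video nor segmentation masks")

    video = bundle.video
    first, last = (0, None)
    if video is not None:
        if cfg.frames is not None:
            first, last = cfg.frames
            if not (0 <= first <= last < video.n_frames):
                raise IndexError(f"frame range {cfg.frames} outside video")
            video = VideoFrames(
                video.frames[first : last + 1], video.frame_rate, video.roi
            )
        if cfg.roi is not None:
            video = _stage("roi")(lambda: apply_roi(video, cfg.roi))

    if bundle.recording is not None:
        fps = video.frame_rate if video is not None else bundle.segmentation.frame_rate

        def align():
            trig = sync_mod.detect_end_trigger(bundle.recording)
            alignment = sync_mod.detect_frame_pulses(bundle.recording, trig, fps=fps)
            n_video = (
                video.n_frames if video is not None else bundle.segmentation.n_frames
            )
            # transferred frames are end-aligned with the detected pulses
            offset = max(alignment.n_frames_detected - n_video, 0)
            lo = offset + first
            hi = offset + (last if last is not None else n_video - 1)
            hi = min(hi, alignment.n_frames_detected - 1)
            seg_audio, _ = sync_mod.extract_audio_segment(
                bundle.recording, alignment, lo, hi
            )
            return alignment, seg_audio

        bundle.alignment, bundle.audio_segment = _stage("sync")(align)
    else:
        log.warning("no audio in bundle; producing a GAW-only report")

    if bundle.segmentation is None:
        if cfg.model is not None:
            bundle.segmentation = _stage("segmentation")(
                lambda: segment_model(video, cfg.model)
            )
        else:
            bundle.segmentation = _stage("segmentation")(
                lambda: segment_threshold(video)
            )
    seg = bundle.segmentation

    bundle.gaw = _stage("gaw")(lambda: waveform_mod.gaw_from_masks(seg))
    bundle.cycles = _stage("cycles")(
        lambda: waveform_mod.detect_cycles(bundle.gaw, cfg.min_prominence_frac)
    )
    if bundle.cycles.n_cycles < cfg.min_cycles and not cfg.force:
        raise TooFewCyclesError(
            f"[parameters] only {bundle.cycles.n_cycles} complete cycles detected; "
            f"at least {cfg.min_cycles} are required (use force to override)"
        )
    _stage("phases")(
        lambda: waveform_mod.decompose_phases(bundle.gaw, bundle.cycles, cfg.closure_eps)
    )
    bundle.midlines = _stage("midline")(
        lambda: midline_mod.estimate_midline(
            seg, bundle.cycles, cfg.midline_method, cfg.context_frames
        )
    )
    bundle.hemi = _stage("hemi")(
        lambda: midline_mod.split_hemi_gaw(seg, bundle.midlines)
    )
    bundle.pvg = _stage("pvg")(
        lambda: pvg_mod.compute_pvg(seg, bundle.midlines, cfg.pvg_stations)
    )
    audio_rate = bundle.recording.sample_rate if bundle.recording else None
    bundle.report = _stage("parameters")(
        lambda: params_mod.compute_report(
            gaw=bundle.gaw,
            cycles=bundle.cycles,
            hemi=bundle.hemi,
            audio=bundle.audio_segment,
            audio_rate=audio_rate,
        )
    )
    return bundle
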