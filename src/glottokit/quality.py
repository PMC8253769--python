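"""Blind (no-reference) image quality scoring with NIQE.

NIQE scores an image by how far the statistics of its locally normalized
luminance (MSCN coefficients and their pairwise products, fitted with
generalized Gaussian distributions per patch) fall from a multivariate
Gaussian model of the same features fitted to pristine images.  Lower is
better; the absolute scale depends on the reference model, which is why
every score is reported next to its model provenance.

The package ships no binary model asset: :func:`fit_niqe_model` fits a
model to any user-provided folder of pristine images, and
:func:`default_model` builds a deterministic reference from seeded
synthetic sharp-edged texture images (labelled synthetic; adequate for
relative comparisons such as distortion monotonicity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate, gaussian_filter
from scipy.special import gamma as gamma_fn

from .errors import InvalidParameterError
from .segmentation import VideoFrames

__all__ = [
    "NiqeModel",
    "mscn_coefficients",
    "extract_features",
    "fit_niqe_model",
    "default_model",
    "niqe_score",
    "niqe_batch",
]

_SHIFTS = ((0, 1), (1, 0), (1, 1), (1, -1))  # H, V, D1, D2 neighbor products

# precomputed grid for inverting the GGD shape-parameter ratio function
_ALPHA_GRID = np.arange(0.2, 10.0, 0.001)
_RHO_GRID = (gamma_fn(2.0 / _ALPHA_GRID) ** 2) / (
    gamma_fn(1.0 / _ALPHA_GRID) * gamma_fn(3.0 / _ALPHA_GRID)
)


@dataclass
class NiqeModel:
    """Multivariate Gaussian of quality-aware features from pristine images."""

    mean: np.ndarray
    cov: np.ndarray
    patch_size: int = 96
    scales: int = 2
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.size
        if self.cov.shape != (d, d):
            raise InvalidParameterError("model covariance shape mismatch")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise InvalidParameterError("model covariance must be symmetric")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "cov": self.cov.tolist(),
                    "patch_size": self.patch_size,
                    "scales": self.scales,
                    "provenance": self.provenance,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "NiqeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"]),
            cov=np.asarray(d["cov"]),
            patch_size=int(d["patch_size"]),
            scales=int(d["scales"]),
            provenance=d.get("provenance", "file"),
        )


def _gaussian_kernel(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img


def mscn_coefficients(
    image: np.ndarray, kernel_size: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted contrast-normalized coefficients and the local sigma.

    ``(I - mu) / (sigma + 1)`` with Gaussian-weighted local mean/std over
    a ``kernel_size`` window; intensities are treated on the 8-bit scale,
    so the +1 stabilizer makes flat regions map to exactly zero.
    """
    img = _to_gray(image)
    if min(img.shape) < 2 * kernel_size:
        raise InvalidParameterError(
            f"image {img.shape} smaller than twice the {kernel_size}px window"
        )
    k = _gaussian_kernel(kernel_size)
    mu = correlate(img, k, mode="nearest")
    sigma = np.sqrt(np.abs(correlate(img * img, k, mode="nearest") - mu * mu))
    return (img - mu) / (sigma + 1.0), sigma


def _ggd_alpha(rho: float) -> float:
    return float(_ALPHA_GRID[np.argmin(np.abs(_RHO_GRID - rho))])

def _fit_ggd(x: np.ndarray) -> tuple[float, float]:
    """Moment-matched generalized Gaussian: (shape alpha, variance)."""
    var = float(np.mean(x**2))
    mean_abs = float(np.mean(np.abs(x)))
    if var == 0 or mean_abs == 0:
        return 10.0, 0.0
    return _ggd_alpha(mean_abs**2 / var), var


def _fit_aggd(x: np.ndarray) -> tuple[float, float, float, float]:
    """Asymmetric GGD fit: (alpha, mean eta, left variance, right variance)."""
    left = x[x < 0]
    right = x[x > 0]
    lsq = float(np.mean(left**2)) if left.size else 1e-12
    rsq = float(np.mean(right**2)) if right.size else 1e-12
    gammahat = np.sqrt(lsq / rsq)
    mean_abs = float(np.mean(np.abs(x)))
    msq = float(np.mean(x**2))
    if msq == 0 or mean_abs == 0:
        return 10.0, 0.0, 0.0, 0.0
    rhat = mean_abs**2 / msq
    rhatnorm = rhat * (gammahat**3 + 1) * (gammahat + 1) / (gammahat**2 + 1) ** 2
    alpha = _ggd_alpha(rhatnorm)
    ratio = gamma_fn(2.0 / alpha) / gamma_fn(1.0 / alpha)
    eta = (np.sqrt(rsq) - np.sqrt(lsq)) * ratio * np.sqrt(
        gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha)
    )
    return alpha, float(eta), lsq, rsq


def _patch_features(mscn: np.ndarray) -> np.ndarray:
    feats = list(_fit_ggd(mscn.ravel()))
    for dy, dx in _SHIFTS:
        prod = mscn * np.roll(np.roll(mscn, dy, axis=0), dx, axis=1)
        feats.extend(_fit_aggd(prod.ravel()))
    return np.asarray(feats)  # 18 per scale


def _downscale(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    c = img[:h, :w]
    return 0.25 * (c[0::2, 0::2] + c[1::2, 0::2] + c[0::2, 1::2] + c[1::2, 1::2])


def extract_features(
    image: np.ndarray,
    patch_size: int = 96,
    scales: int = 2,
    sharpness_threshold: float | None = None,
) -> np.ndarray:
    """Per-patch quality-aware feature vectors (n_patches x 18*scales).

    The image is tiled into non-overlapping ``patch_size`` blocks; each
    block yields 18 GGD/AGGD features per scale (the block shrinks with
    the image at each scale so features describe the same region).  With
    ``sharpness_threshold`` set, only blocks whose mean local activity at
    full resolution exceeds that fraction of the sharpest block are kept
    (used when fitting pristine models).
    """
    img = _to_gray(image)
    mscn0, sigma0 = mscn_coefficients(img)
    H, W = img.shape
    ps = patch_size
    ny, nx = H // ps, W // ps
    if ny * nx < 1:
        raise InvalidParameterError(
            f"image {img.shape} too small for {ps}px patches"
        )
    sharp = np.array(
        [
            sigma0[i * ps : (i + 1) * ps, j * ps : (j + 1) * ps].mean()
            for i in range(ny)
            for j in range(nx)
        ]
    )
    if sharpness_threshold is not None and sharp.max() > 0:
        keep = sharp >= sharpness_threshold * sharp.max()
    else:
        keep = np.ones(sharp.size, dtype=bool)

    per_scale = []
    cur = img
    for s in range(scales):
        p = ps >> s
        mscn, _ = mscn_coefficients(cur)
        feats = np.stack(
            [
                _patch_features(mscn[i * p : (i + 1) * p, j * p : (j + 1) * p])
                for i in range(ny)
                for j in range(nx)
            ]
        )
        per_scale.append(feats)
        cur = _downscale(cur)
    return np.hstack(per_scale)[keep]


def fit_niqe_model(
    images: list[np.ndarray],
    patch_size: int = 96,
    scales: int = 2,
    sharpness_threshold: float = 0.75,
    provenance: str = "user",
) -> NiqeModel:
    """Fit the multivariate Gaussian reference from pristine images."""
    feats = np.vstack(
        [
            extract_features(im, patch_size, scales, sharpness_threshold)
            for im in images
        ]
    )
    if feats.shape[0] < 2 * feats.shape[1]:
        # few patches: shrink toward the diagonal for a stable covariance
        cov = np.cov(feats, rowvar=False)
        cov = cov + 0.01 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    else:
        cov = np.cov(feats, rowvar=False)
    return NiqeModel(
        mean=feats.mean(axis=0),
        cov=cov,
        patch_size=patch_size,
        scales=scales,
        provenance=provenance,
    )


def fractal_texture(
    rng: np.random.Generator, size: int, jitter: bool = True
) -> np.ndarray:
    """Unit-variance multi-scale (fractal) texture field.

    A sum of Gaussian-filtered white-noise layers at octave scales with
    a ~scale^0.7 amplitude law: textured at every scale with no white
    (single-pixel) component, mimicking natural-scene second-order
    statistics.
    """
    img = np.zeros((size, size))
    for sigma in (1.0, 2.0, 4.0, 8.0, 16.0):
        layer = gaussian_filter(rng.normal(size=(size, size)), sigma)
        layer /= max(layer.std(), 1e-9)
        w = rng.uniform(0.6, 1.4) if jitter else 1.0
        img += w * sigma**0.7 * layer
    return img / max(img.std(), 1e-9)


def _synthetic_pristine(rng: np.random.Generator, size: int = 384) -> np.ndarray:
    """One synthetic stand-in for a pristine natural scene.

    Fractal texture (content at every scale), a few dark high-contrast
    elliptical regions (shadowed cavities -- the statistics of dark
    openings on bright tissue), mild contrast diversity, and a small
    optics-like point-spread blur so the family spans realistic, not
    aliased, sharpness.
    """
    img = 128.0 + 55.0 * fractal_texture(rng, size) * rng.uniform(0.6, 1.2)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(int(rng.integers(1, 4))):
        cy, cx = rng.uniform(0.2, 0.8, 2) * size
        a, b = rng.uniform(10, 60, 2)
        th = rng.uniform(0, np.pi)
        u = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        v = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        img[(u / a) ** 2 + (v / b) ** 2 <= 1] = rng.uniform(10, 40)
    return np.clip(gaussian_filter(img, rng.uniform(0.3, 0.6)), 0, 255)


@lru_cache(maxsize=2)
def default_model(seed: int = 1234, n_images: int = 24) -> NiqeModel:
    """Deterministic reference model from synthetic pristine textures."""
    rng = np.random.default_rng(seed)
    images = [_synthetic_pristine(rng) for _ in range(n_images)]
    return fit_niqe_model(
        images, provenance=f"synthetic-textures(seed={seed}, n={n_images})"
    )


def score_features(
    nu: np.ndarray, cov_test: np.ndarray, model: NiqeModel
) -> float:
    """Mahalanobis-type distance between a test feature Gaussian and the model."""
    diff = np.asarray(nu, dtype=float) - model.mean
    pooled = (model.cov + np.asarray(cov_test, dtype=float)) / 2.0
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular pooled covariance; using pseudo-inverse",
                      stacklevel=2)
        sol = np.linalg.pinv(pooled) @ diff
    return float(np.sqrt(max(diff @ sol, 0.0)))


def niqe_score(image: np.ndarray, model: NiqeModel | None = None) -> float:
    """NIQE score of one image (lower = better quality)."""
    model = model or default_model()
    feats = extract_features(image, model.patch_size, model.scales)
    if feats.shape[0] < 4:
        raise InvalidParameterError(
            "need at least 4 patches; provide a larger image"
        )
    return score_features(feats.mean(axis=0), np.cov(feats, rowvar=False), model)


def niqe_batch(
    video: VideoFrames, model: NiqeModel | None = None, stride: int = 1
) -> dict:
    """Score every ``stride``-th frame; returns scores, mean and provenance."""
    model = model or default_model()
    if video.n_frames < 1:
        raise InvalidParameterError("empty video")
    idx = np.arange(0, video.n_frames, max(int(stride), 1))
    scores = np.array([niqe_score(video.frames[i], model) for i in idx])
    return {
        "frame_indices": idx,
        "scores": scores,
        "mean": float(scores.mean()),
        "std": float(scores.std()),
        "model_provenance": model.provenance,
    }
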