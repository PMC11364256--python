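"""Frame preprocessing, augmentation cascade and frame-sampling policies.

Raw clips are converted to the network's input representation: grayscale in
[0, 1], resized to a fixed height with preserved aspect ratio, then
center-cropped to a square.  Training-time augmentation is a cascade of five
random transforms (rotation, gamma, resized crop, elastic distortion,
additive Gaussian noise), each independently applied with 50% probability,
with one parameter draw shared by all frames of a clip so temporal
consistency is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
from scipy import ndimage

from .synthdata import VideoClip

__all__ = [
    "PreprocessConfig",
    "to_grayscale",
    "crop_resize_center",
    "augment",
    "sample_frames",
    "preprocess_clip",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform toggles and parameter ranges for the cascade."""

    probability: float = 0.5
    rotation: bool = True
    rotation_deg: float = 25.0
    gamma: bool = True
    gamma_range: tuple[float, float] = (0.5, 2.0)
    resized_crop: bool = True
    crop_scale_range: tuple[float, float] = (0.2, 2.0)
    elastic: bool = True
    elastic_alpha: float = 2.0
    elastic_sigma: float = 8.0
    noise: bool = True
    noise_sigma: float = 0.01


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 224
    crop_region: tuple[int, int, int, int] | None = None  # (top, left, height, width)
    train_frames_per_clip: int = 8
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Convert T x H x W x C pixel data in [0, 255] to grayscale in [0, 1].

    Conversion is the unweighted channel mean divided by 255 (no luma
    weights): this matches averaging an RGB input layer's weights into a
    single channel.  Single-channel input is passed through after rescaling.
    """
    f = np.asarray(frames, dtype=np.float64)
    if f.ndim != 4 or f.shape[-1] not in (1, 3):
        raise ValueError("expected T x H x W x C with C in {1, 3}")
    if f.min() < 0 or f.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    if f.shape[-1] == 1:
        g = f[..., 0]
        return g if g.max() <= 1.0 else g / 255.0  # pass-through if rescaled
    return f.mean(axis=-1) / 255.0


def crop_resize_center(frames: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Optional rectangle crop, resize to target height (aspect preserved,
    bilinear), then central square crop of the target width; widths below the
    target are symmetrically zero-padded instead of stretched."""
    cfg = cfg or PreprocessConfig()
    f = np.asarray(frames, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("expected T x H x W")
    T, H, W = f.shape
    if H < 2 or W < 2:
        raise ValueError("frames too small")

    if cfg.crop_region is not None:
        top, left, h, w = cfg.crop_region
        if top < 0 or left < 0 or h < 2 or w < 2 or top + h > H or left + w > W:
            raise ValueError("crop_region outside frame bounds")
        f = f[:, top:top + h, left:left + w]
        H, W = h, w

    s = cfg.target_size
    new_w = max(1, int(round(W * s / H)))
    if (H, W) != (s, new_w):
        f = _bilinear_resize(f, s, new_w)
    if new_w >= s:
        left = (new_w - s) // 2
        f = f[:, :, left:left + s]
    else:
        pad = s - new_w
        lpad = pad // 2
        f = np.pad(f, ((0, 0), (0, 0), (lpad, pad - lpad)))
    return np.clip(f, 0.0, 1.0)


@lru_cache(maxsize=16)
def _resize_weights(n_in: int, n_out: int):
    # pixel-center-aligned bilinear sampling with edge clamping
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = np.clip(src - i0, 0.0, 1.0)
    return i0, i1, w


def _bilinear_resize(frames: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize of a T x H x W stack."""
    T, H, W = frames.shape
    i0, i1, wy = _resize_weights(H, out_h)
    j0, j1, wx = _resize_weights(W, out_w)
    tmp = frames[:, i0, :] * (1 - wy)[None, :, None] + frames[:, i1, :] * wy[None, :, None]
    return tmp[:, :, j0] * (1 - wx) + tmp[:, :, j1] * wx


def _rotate(frames: np.ndarray, angle_deg: float) -> np.ndarray:
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        out[t] = ndimage.rotate(frames[t], angle_deg, reshape=False, order=1,
                                mode="constant", cval=0.0)
    return out


def _resized_crop(frames: np.ndarray, scale: float, cy: float, cx: float) -> np.ndarray:
    """Zoom by ``scale`` about a relative center (cy, cx) in [0, 1]."""
    T, H, W = frames.shape
    # output pixel o maps to input i = o/scale + shift, keeping the chosen
    # center fixed; scale > 1 zooms in (crop), scale < 1 zooms out (pad)
    shift_y = cy * H * (1 - 1 / scale)
    shift_x = cx * W * (1 - 1 / scale)
    matrix = np.diag([1 / scale, 1 / scale])
    out = np.empty_like(frames)
    for t in range(T):
        out[t] = ndimage.affine_transform(
            frames[t], matrix, offset=(shift_y, shift_x), order=1,
            mode="constant", cval=0.0)
    return out


def _elastic(frames: np.ndarray, alpha: float, sigma: float,
             rng: np.random.Generator) -> np.ndarray:
    T, H, W = frames.shape
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (H, W)), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (H, W)), sigma) * alpha
    ys, xs = np.mgrid[0:H, 0:W].astype(np.float64)
    coords = np.array([ys + dy, xs + dx])
    out = np.empty_like(frames)
    for t in range(T):
        out[t] = ndimage.map_coordinates(frames[t], coords, order=1,
                                         mode="constant", cval=0.0)
    return out


def augment(frames: np.ndarray, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> np.ndarray:
    """Apply the augmentation cascade to all frames of one clip.

    Transforms run in a fixed order -- rotation, gamma, resized crop,
    elastic distortion, additive noise -- each gated by an independent fair
    coin, with a single parameter draw shared across the clip's frames.
    Output is clipped to [0, 1] and shape-preserving.
    """
    cfg = cfg or AugmentConfig()
    f = np.asarray(frames, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("expected T x H x W")
    if f.min() < 0 or f.max() > 1:
        raise ValueError("input must lie in [0, 1]")
    p = cfg.probability

    if cfg.rotation and rng.random() < p:
        angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        f = _rotate(f, angle)
    if cfg.gamma and rng.random() < p:
        gamma = float(rng.uniform(*cfg.gamma_range))
        f = np.clip(f, 0.0, 1.0) ** gamma
    if cfg.resized_crop and rng.random() < p:
        scale = float(rng.uniform(*cfg.crop_scale_range))
        cy, cx = rng.uniform(0.3, 0.7, size=2)
        f = _resized_crop(f, scale, float(cy), float(cx))
    if cfg.elastic and rng.random() < p:
        f = _elastic(f, cfg.elastic_alpha, cfg.elastic_sigma, rng)
    if cfg.noise and rng.random() < p:
        f = f + rng.normal(0.0, cfg.noise_sigma, f.shape)
    return np.clip(f, 0.0, 1.0)


def sample_frames(frames: np.ndarray, mode: str, n: int | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Frame-sampling policy.

    ``train``: n indices sampled uniformly without replacement (with
    replacement when the clip is shorter than n), returned in ascending
    temporal order.  ``test``: the full sequence in original order.
    """
    f = np.asarray(frames)
    if f.ndim != 3 or f.shape[0] < 1:
        raise ValueError("expected non-empty T x H x W")
    T = f.shape[0]
    if mode == "test":
        return f
    if mode != "train":
        raise ValueError("mode must be 'train' or 'test'")
    if n is None or n < 1:
        raise ValueError("train mode requires n >= 1")
    if rng is None:
        raise ValueError("train mode requires an rng")
    if T >= n:
        idx = rng.choice(T, size=n, replace=False)
    else:
        idx = rng.integers(0, T, size=n)
    return f[np.sort(idx)]


def preprocess_clip(clip: VideoClip, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Resize/crop a clip's frames to the network input grid (no sampling)."""
    return crop_resize_center(np.asarray(clip.frames, dtype=np.float64), cfg)
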