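"""Synthetic ultrasound-style phantom videos for open-set view recognition.

This module generates labeled grayscale video clips that mimic the coarse
geometry of B-mode echocardiography: a sector-fan field of view containing a
small number of bright-walled, dark-interior "chambers" (ellipses) that
pulsate over a cardiac cycle, with multiplicative speckle texture.  Each
known view class is a distinct chamber layout; three unknown subcategories
are generated on top of the known layouts:

* ``novel_category`` — a reserved chamber layout never assigned to a known
  class, rendered at normal quality;
* ``poor_quality`` — a known layout rendered with structure visibility forced
  below a floor, so the view is unidentifiable;
* ``multiple_views`` — the layout switches from one known class to a
  different one mid-clip.

Every clip carries a ground-truth quality score in [0, 1], a fixed convex
combination of the four degradation knobs (visibility, centering, gain,
depth), mirroring questionnaire-style quality ratings normalized to [0, 1].

The generator is deliberately not a physical ultrasound simulator: there is
no wave propagation or transducer model, just enough structure for a frame
classifier to have a solvable, well-separated task.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN_LABELS",
    "OUTLIER_LABEL",
    "LayoutSpec",
    "QualityParams",
    "VideoClip",
    "GeneratorConfig",
    "DatasetConfig",
    "SplitDataset",
    "make_view_layout",
    "render_frame",
    "true_quality",
    "generate_video",
    "generate_dataset",
    "sample_quality_params",
    "generate_quality_set",
    "save_dataset",
    "load_dataset",
    "export_clip_png",
]

UNKNOWN_LABELS = ("novel_category", "poor_quality", "multiple_views")
#: label used when unknown clips are collapsed into one training class
OUTLIER_LABEL = "outlier"

# sector-fan geometry (fractions of the frame): apex at top-center, fixed
# 75 degree aperture -- visual convention only, irrelevant to the method.
_APEX = (0.5, 0.05)  # (x, y)
_APERTURE_DEG = 75.0
_RADIUS = 0.88
_R_MIN = 0.03
_SECTOR_CENTER = (0.5, 0.5)

_BACKGROUND = 0.35  # nominal in-sector background level before gain/speckle


@dataclass(frozen=True)
class LayoutSpec:
    """Chamber layout of one view class.

    ``ellipses`` is a list of tuples ``(cx, cy, ax, ay, angle, wall)`` in
    fractions of the frame: center, semi-axes, orientation (radians) and wall
    brightness in [0, 1].
    """

    class_id: int
    ellipses: tuple[tuple[float, float, float, float, float, float], ...]
    motion_amplitude: float = 0.06
    cycle_length: int = 16

    def __post_init__(self):
        for (cx, cy, ax, ay, _ang, wall) in self.ellipses:
            if ax <= 0 or ay <= 0:
                raise ValueError("ellipse axes must be positive")
            if not (0.0 <= wall <= 1.0):
                raise ValueError("wall brightness must be in [0, 1]")
            if not _inside_sector(cx, cy):
                raise ValueError(f"ellipse center ({cx:.3f},{cy:.3f}) outside sector")


@dataclass(frozen=True)
class QualityParams:
    """Degradation knobs of one clip; all in [0, 1] except speckle_strength.

    ``centering_angle`` is the direction (radians) of the centering
    displacement; it is rendering detail only and does not enter the quality
    score.
    """

    visibility: float = 1.0
    centering_offset: float = 0.0
    gain_deviation: float = 0.0
    depth_error: float = 0.0
    speckle_strength: float = 0.3
    centering_angle: float = 0.0

    def __post_init__(self):
        for name in ("visibility", "centering_offset", "gain_deviation", "depth_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")


Label = Union[int, str]


@dataclass
class VideoClip:
    """A T x H x W stack of pixel intensities in [0, 1] plus label metadata."""

    frames: np.ndarray
    label: Label
    true_quality: float | None = None
    frame_rate: float = 50.0
    clip_id: str = ""

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if f.min() < 0.0 or f.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if isinstance(self.label, str) and self.label not in UNKNOWN_LABELS + (OUTLIER_LABEL,):
            raise ValueError(f"unrecognized label {self.label!r}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def is_known(self) -> bool:
        return not isinstance(self.label, str)


@dataclass(frozen=True)
class GeneratorConfig:
    """Static geometry/configuration of the phantom generator."""

    n_known: int = 10
    n_novel: int = 2
    frame_size: int = 256
    layout_seed: int = 0
    poor_quality_floor: float = 0.1
    frame_rate: float = 50.0

    @property
    def n_total(self) -> int:
        return self.n_known + self.n_novel


def _inside_sector(x: float, y: float) -> bool:
    dx, dy = x - _APEX[0], y - _APEX[1]
    r = np.hypot(dx, dy)
    if r < _R_MIN or r > _RADIUS:
        return False
    ang = np.degrees(np.arctan2(dx, dy))  # 0 = straight down
    return abs(ang) <= _APERTURE_DEG / 2


def _clamp_into_sector(x: float, y: float) -> tuple[float, float]:
    """Pull a point toward the sector center until it lies inside the fan."""
    cx, cy = _SECTOR_CENTER
    for t in np.linspace(0.0, 1.0, 41):
        px, py = x + t * (cx - x), y + t * (cy - y)
        if _inside_sector(px, py):
            return float(px), float(py)
    return cx, cy


def make_view_layout(class_id: int, seed: int = 0, config: GeneratorConfig | None = None) -> LayoutSpec:
    """Deterministic chamber layout for one view class.

    Distinct class ids are separable by construction: the chamber count
    cycles with ``class_id % 3`` and, within one count group, the anchor
    chamber sits on a circle around the sector center at an angle set by
    ``class_id // 3``, so anchors of same-count classes are >= 0.18 frame
    fractions apart (jitter is +/- 0.015 per coordinate).
    """
    config = config or GeneratorConfig()
    if not (0 <= class_id < config.n_total):
        raise ValueError(f"class_id {class_id} outside [0, {config.n_total})")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, class_id])

    n_ellipses = 2 + (class_id % 3)
    anchor_angle = (class_id // 3) * (np.pi / 2) + np.pi / 8
    jitter = lambda: rng.uniform(-0.015, 0.015)  # noqa: E731

    cx0 = _SECTOR_CENTER[0] + 0.16 * np.cos(anchor_angle) + jitter()
    cy0 = _SECTOR_CENTER[1] + 0.16 * np.sin(anchor_angle) + jitter()
    cx0, cy0 = _clamp_into_sector(cx0, cy0)

    ellipses = [(
        cx0, cy0,
        float(rng.uniform(0.09, 0.13)), float(rng.uniform(0.06, 0.09)),
        float(rng.uniform(0, np.pi)), float(rng.uniform(0.75, 0.95)),
    )]
    for k in range(1, n_ellipses):
        sat_angle = anchor_angle + np.pi * (0.55 + 0.9 * k / n_ellipses) + rng.uniform(-0.1, 0.1)
        cx = cx0 + 0.15 * np.cos(sat_angle) + jitter()
        cy = cy0 + 0.15 * np.sin(sat_angle) + jitter()
        cx, cy = _clamp_into_sector(cx, cy)
        ellipses.append((
            cx, cy,
            float(rng.uniform(0.05, 0.08)), float(rng.uniform(0.035, 0.06)),
            float(rng.uniform(0, np.pi)), float(rng.uniform(0.7, 0.9)),
        ))
    return LayoutSpec(class_id=class_id, ellipses=tuple(ellipses))


def layouts_separable(a: LayoutSpec, b: LayoutSpec, min_dist: float = 0.1) -> bool:
    """True if two layouts differ in ellipse count or anchor center by >= min_dist."""
    if len(a.ellipses) != len(b.ellipses):
        return True
    (ax, ay) = a.ellipses[0][:2]
    (bx, by) = b.ellipses[0][:2]
    return float(np.hypot(ax - bx, ay - by)) >= min_dist


@lru_cache(maxsize=8)
def _grids(size: int) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0:size, 0:size]
    return ((xs + 0.5) / size).astype(np.float32), ((ys + 0.5) / size).astype(np.float32)


@lru_cache(maxsize=8)
def sector_mask(size: int) -> np.ndarray:
    """Boolean H x W sector-fan mask (True inside the imaging fan)."""
    x, y = _grids(size)
    dx, dy = x - _APEX[0], y - _APEX[1]
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dx, dy))
    return (r >= _R_MIN) & (r <= _RADIUS) & (np.abs(ang) <= _APERTURE_DEG / 2)


def true_quality(q: QualityParams) -> float:
    """Ground-truth quality score in [0, 1].

    Fixed convex combination 0.4*visibility + 0.2*(1-centering_offset)
    + 0.2*(1-gain_deviation) + 0.2*(1-depth_error): monotone increasing in
    visibility and decreasing in each degradation.
    """
    return float(
        0.4 * q.visibility
        + 0.2 * (1.0 - q.centering_offset)
        + 0.2 * (1.0 - q.gain_deviation)
        + 0.2 * (1.0 - q.depth_error)
    )


def render_frame(
    layout: LayoutSpec,
    phase: float,
    q: QualityParams,
    rng: np.random.Generator,
    size: int = 256,
) -> np.ndarray:
    """Render one H x W frame in [0, 1].

    Pixels outside the sector fan are exactly 0.  Chamber walls are brighter
    and interiors darker than the background by margins proportional to
    ``q.visibility``; speckle is multiplicative log-normal noise, normalized
    to unit mean, applied before clipping.
    """
    if size < 64:
        raise ValueError("frame size must be >= 64")
    mask = sector_mask(size)
    x, y = _grids(size)

    img = np.full((size, size), _BACKGROUND, dtype=np.float32)

    # quality-driven geometry: centering displacement and depth (scale) error
    off = 0.22 * q.centering_offset
    tx = off * np.cos(q.centering_angle)
    ty = off * np.sin(q.centering_angle)
    scale = 1.0 - 0.45 * q.depth_error
    scx, scy = _SECTOR_CENTER

    vis = q.visibility
    for k, (cx, cy, ax, ay, ang, wall) in enumerate(layout.ellipses):
        pul = 1.0 + layout.motion_amplitude * np.sin(2 * np.pi * (phase + 0.2 * k))
        ecx = scx + scale * (cx - scx) + tx
        ecy = scy + scale * (cy - scy) + ty
        eax = ax * scale * pul
        eay = ay * scale * pul
        # rasterize only within the ellipse's bounding box
        rad = 1.1 * max(eax, eay)
        i0 = max(0, int((ecy - rad) * size) - 1)
        i1 = min(size, int((ecy + rad) * size) + 2)
        j0 = max(0, int((ecx - rad) * size) - 1)
        j1 = min(size, int((ecx + rad) * size) + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = x[i0:i1, j0:j1] - np.float32(ecx)
        dy = y[i0:i1, j0:j1] - np.float32(ecy)
        u = ((dx * np.cos(ang) + dy * np.sin(ang)) / eax) ** 2 + (
            (-dx * np.sin(ang) + dy * np.cos(ang)) / eay
        ) ** 2
        sub = img[i0:i1, j0:j1]
        sub[u < 0.7] = _BACKGROUND * (1.0 - 0.8 * vis)
        band = (u >= 0.7) & (u <= 1.15)
        sub[band] = _BACKGROUND + vis * (wall - _BACKGROUND)

    img *= np.float32(1.0 - 0.5 * q.gain_deviation)  # under-gain: darker
    if q.speckle_strength > 0:
        s = q.speckle_strength
        speckle = np.exp(rng.normal(-s * s / 2.0, s, img.shape)).astype(np.float32)
        img *= speckle
    img = np.clip(img, 0.0, 1.0)
    img[~mask] = 0.0
    return img


def _known_layouts(config: GeneratorConfig) -> list[LayoutSpec]:
    return [make_view_layout(c, config.layout_seed, config) for c in range(config.n_known)]


def generate_video(
    kind: Label,
    T: int,
    q: QualityParams,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> VideoClip:
    """Generate one labeled clip.

    ``kind`` is a known class id, or one of the unknown subcategory labels.
    Known clips animate a single known layout over the cardiac phase; novel
    clips use a reserved layout never assigned to a known class; poor-quality
    clips force visibility below the configured floor; multiple-view clips
    switch between two distinct known layouts at a frame index drawn
    uniformly from [T/4, 3T/4).
    """
    config = config or GeneratorConfig()
    if T < 1:
        raise ValueError("T must be >= 1")

    if isinstance(kind, str) and kind == "multiple_views":
        if T < 2:
            raise ValueError("multiple_views requires T >= 2")
        if config.n_known < 2:
            raise ValueError("multiple_views requires >= 2 known classes")

    if isinstance(kind, (int, np.integer)):
        if not (0 <= kind < config.n_known):
            raise ValueError(f"known class id {kind} outside [0, {config.n_known})")
        layouts = [make_view_layout(int(kind), config.layout_seed, config)]
        switch = None
        label: Label = int(kind)
    elif kind == "novel_category":
        novel_id = config.n_known + int(rng.integers(config.n_novel))
        layouts = [make_view_layout(novel_id, config.layout_seed, config)]
        switch = None
        label = kind
    elif kind == "poor_quality":
        cid = int(rng.integers(config.n_known))
        layouts = [make_view_layout(cid, config.layout_seed, config)]
        switch = None
        q = dataclasses.replace(q, visibility=min(q.visibility, config.poor_quality_floor))
        label = kind
    elif kind == "multiple_views":
        a, b = rng.choice(config.n_known, size=2, replace=False)
        layouts = [
            make_view_layout(int(a), config.layout_seed, config),
            make_view_layout(int(b), config.layout_seed, config),
        ]
        lo, hi = T // 4, max(T // 4 + 1, (3 * T) // 4)
        switch = int(rng.integers(lo, hi))
        switch = max(1, min(T - 1, switch))
        label = kind
    else:
        raise ValueError(f"unrecognized kind {kind!r}")

    frames = np.empty((T, config.frame_size, config.frame_size), dtype=np.float32)
    for t in range(T):
        layout = layouts[0] if switch is None or t < switch else layouts[1]
        phase = (t % layout.cycle_length) / layout.cycle_length
        frames[t] = render_frame(layout, phase, q, rng, size=config.frame_size)
    return VideoClip(
        frames=frames,
        label=label,
        true_quality=true_quality(q),
        frame_rate=config.frame_rate,
    )


def sample_quality_params(
    rng: np.random.Generator,
    visibility_range: tuple[float, float] = (0.75, 1.0),
    centering_range: tuple[float, float] = (0.0, 0.15),
    gain_range: tuple[float, float] = (0.0, 0.15),
    depth_range: tuple[float, float] = (0.0, 0.15),
    speckle: float = 0.3,
) -> QualityParams:
    """Draw per-clip quality knobs; defaults emulate routine acquisitions."""
    return QualityParams(
        visibility=float(rng.uniform(*visibility_range)),
        centering_offset=float(rng.uniform(*centering_range)),
        gain_deviation=float(rng.uniform(*gain_range)),
        depth_error=float(rng.uniform(*depth_range)),
        speckle_strength=speckle,
        centering_angle=float(rng.uniform(0, 2 * np.pi)),
    )


@dataclass(frozen=True)
class DatasetConfig:
    """Counts, quality distributions and unknown fractions per split.

    The training split never contains unknown-labeled clips; validation and
    test carry all three unknown subcategories at ``unknown_fraction`` of
    their known-clip count.  ``outlier_exposure`` adds unknown clips to the
    training split collapsed to the single :data:`OUTLIER_LABEL` class.
    """

    n_classes: int = 10
    train_per_class: int = 50
    val_per_class: int = 8
    test_per_class: int = 8
    unknown_fraction: float = 0.3
    outlier_exposure: bool = False
    frames_per_clip: int = 12
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    visibility_range: tuple[float, float] = (0.75, 1.0)

    def __post_init__(self):
        if self.n_classes < 1 or self.train_per_class < 1:
            raise ValueError("per-class counts must be >= 1")
        if self.n_classes > self.generator.n_known:
            raise ValueError("n_classes exceeds generator's known layouts")


@dataclass
class SplitDataset:
    train: list[VideoClip]
    val: list[VideoClip]
    test: list[VideoClip]

    def split(self, name: str) -> list[VideoClip]:
        return getattr(self, name)


_SPLIT_OFFSETS = {"train": 0, "val": 1, "test": 2}


def _unknown_counts(n_known_clips: int, fraction: float) -> dict[str, int]:
    # at least one clip per subcategory so every split exercises all three
    total = max(3, int(round(fraction * n_known_clips)))
    base, extra = divmod(total, 3)
    return {
        lab: base + (1 if i < extra else 0)
        for i, lab in enumerate(UNKNOWN_LABELS)
    }


def _generate_split(
    name: str,
    per_class: int,
    cfg: DatasetConfig,
    seed: int,
    with_unknowns: bool,
    collapse_outliers: bool = False,
) -> list[VideoClip]:
    rng = np.random.default_rng(seed + _SPLIT_OFFSETS[name])
    clips: list[VideoClip] = []
    T = cfg.frames_per_clip
    for c in range(cfg.n_classes):
        for i in range(per_class):
            q = sample_quality_params(rng, visibility_range=cfg.visibility_range)
            clip = generate_video(c, T, q, rng, cfg.generator)
            clip.clip_id = f"{name}-k{c}-{i}"
            clips.append(clip)
    if with_unknowns:
        counts = _unknown_counts(cfg.n_classes * per_class, cfg.unknown_fraction)
        for lab, n in counts.items():
            for i in range(n):
                q = sample_quality_params(rng, visibility_range=cfg.visibility_range)
                clip = generate_video(lab, max(T, 2), q, rng, cfg.generator)
                if collapse_outliers:
                    clip.label = OUTLIER_LABEL
                clip.clip_id = f"{name}-{lab}-{i}"
                clips.append(clip)
    return clips


def generate_dataset(config: DatasetConfig, seed: int = 0) -> SplitDataset:
    """Generate train/val/test splits with disjoint per-split seeds.

    Unknown-labeled clips appear only in validation and test, unless
    ``config.outlier_exposure`` requests a collapsed outlier class in the
    training split.
    """
    train = _generate_split(
        "train", config.train_per_class, config, seed,
        with_unknowns=config.outlier_exposure, collapse_outliers=True,
    )
    val = _generate_split("val", config.val_per_class, config, seed, with_unknowns=True)
    test = _generate_split("test", config.test_per_class, config, seed, with_unknowns=True)
    return SplitDataset(train=train, val=val, test=test)


def generate_quality_set(
    n_per_class: int,
    seed: int,
    config: GeneratorConfig | None = None,
    n_classes: int | None = None,
    frames_per_clip: int = 12,
) -> list[VideoClip]:
    """Quality-labeled clips spanning the full degradation range.

    Emulates a questionnaire-rated subset: every clip is a known view, with
    visibility, centering, gain and depth knobs drawn over wide ranges so
    the ground-truth score covers most of [0, 1].
    """
    config = config or GeneratorConfig()
    n_classes = n_classes or config.n_known
    rng = np.random.default_rng(seed)
    clips = []
    for c in range(n_classes):
        for i in range(n_per_class):
            q = sample_quality_params(
                rng,
                visibility_range=(0.15, 1.0),
                centering_range=(0.0, 0.6),
                gain_range=(0.0, 0.7),
                depth_range=(0.0, 0.6),
            )
            clip = generate_video(c, frames_per_clip, q, rng, config)
            clip.clip_id = f"qa-k{c}-{i}"
            clips.append(clip)
    return clips


# ---------------------------------------------------------------------------
# dataset directory I/O: one compressed array container per clip plus a CSV
# sidecar (clip_id, label, true_quality, frame_rate, split)

def save_dataset(ds: SplitDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for split in ("train", "val", "test"):
        for i, clip in enumerate(ds.split(split)):
            cid = clip.clip_id or f"{split}-{i:05d}"
            np.savez_compressed(out / f"{cid}.npz", frames=clip.frames.astype(np.float32))
            rows.append({
                "clip_id": cid,
                "label": clip.label,
                "true_quality": clip.true_quality,
                "frame_rate": clip.frame_rate,
                "split": split,
            })
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)


def load_dataset(in_dir: str | Path) -> SplitDataset:
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    splits: dict[str, list[VideoClip]] = {"train": [], "val": [], "test": []}
    for row in meta.itertuples():
        frames = np.load(src / f"{row.clip_id}.npz")["frames"]
        label: Label = row.label
        try:
            label = int(label)
        except (TypeError, ValueError):
            label = str(label)
        tq = None if pd.isna(row.true_quality) else float(row.true_quality)
        clip = VideoClip(frames=frames, label=label, true_quality=tq,
                         frame_rate=float(row.frame_rate), clip_id=str(row.clip_id))
        splits[str(row.split)].append(clip)
    return SplitDataset(**splits)


def export_clip_png(clip: VideoClip, out_dir: str | Path) -> list[Path]:
    """Write a clip's frames as 8-bit PNGs for visual inspection."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(clip.n_frames):
        p = out / f"frame_{t:04d}.png"
        iio.imwrite(p, (np.asarray(clip.frames[t]) * 255).astype(np.uint8))
        paths.append(p)
    return paths
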