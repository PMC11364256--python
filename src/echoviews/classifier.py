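"""Frame-level view classifier with video-level aggregation.

The classifier processes each frame of a video independently with a 2D CNN,
producing a class-logit vector per frame.  Video-level outputs are temporal
arithmetic means: the mean logit vector (whose argmax is the view
prediction and whose maximum is the max-logit anomaly score) and the mean
penultimate feature vector (used by the quality head).

Training follows the cross-entropy / AdamW recipe with class-balanced
sampling with replacement, an epoch defined as ceil(N / batch) iterations,
and a step learning-rate schedule.  An optional outlier-exposure variant
appends one extra logit for a collapsed outlier class; that logit is never
emitted as a view prediction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .network import AdamW, SmallCNN, cross_entropy
from .preprocess import PreprocessConfig, augment, preprocess_clip, sample_frames
from .synthdata import OUTLIER_LABEL, VideoClip

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "TrainedModel",
    "desk_train_config",
    "build_model",
    "forward_frames",
    "aggregate_logits",
    "aggregate_features",
    "predict_view",
    "make_balanced_sampler",
    "lr_at_epoch",
    "train_classifier",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BackboneConfig:
    architecture: str = "small_cnn"  # or "resnet50_v2"
    normalization: str = "group_norm"  # or "batch_norm"
    weight_standardization: bool = False
    num_known_classes: int = 10
    outlier_exposure: bool = False
    embedding_dim: int = 128

    def __post_init__(self):
        if self.num_known_classes < 2:
            raise ValueError("need at least 2 known classes")
        if self.embedding_dim < 8:
            raise ValueError("embedding_dim must be >= 8")

    @property
    def n_logits(self) -> int:
        return self.num_known_classes + (1 if self.outlier_exposure else 0)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the full-scale recipe and are
    all overridable for desk-scale runs."""

    batch_videos: int = 16
    frames_per_video: int = 8
    epochs: int = 300
    lr: float = 1e-4
    lr_drop_epochs: tuple[int, ...] = (150, 250)
    lr_drop_factor: float = 10.0
    betas: tuple[float, float] = (0.0, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    balanced_sampling: bool = True
    augment: bool = True
    seed: int = 0
    val_every: int = 0  # 0 = only log training metrics


def desk_train_config(seed: int = 0, epochs: int = 12) -> TrainConfig:
    """Desk-scale settings used by the synthetic benchmark: fewer epochs,
    a proportionally scaled LR schedule and a larger LR suited to a small
    from-scratch CNN."""
    d1 = max(1, int(epochs * 0.6))
    d2 = max(d1 + 1, int(epochs * 0.85))
    return TrainConfig(epochs=epochs, lr=1e-3, lr_drop_epochs=(d1, d2),
                       augment=False, seed=seed)


def build_model(cfg: BackboneConfig, seed: int = 0) -> SmallCNN:
    if cfg.architecture == "resnet50_v2":
        raise NotImplementedError(
            "resnet50_v2 is reserved for full-scale replication and is not "
            "provided by the built-in NumPy engine; use architecture='small_cnn'")
    if cfg.architecture != "small_cnn":
        raise ValueError(f"unknown architecture {cfg.architecture!r}")
    return SmallCNN(
        n_out=cfg.n_logits,
        embedding_dim=cfg.embedding_dim,
        norm=cfg.normalization,
        weight_standardization=cfg.weight_standardization,
        seed=seed,
    )


@dataclass
class TrainedModel:
    model: SmallCNN
    backbone: BackboneConfig
    train_config: TrainConfig | None = None
    log: list[dict] = field(default_factory=list)

    @property
    def num_known_classes(self) -> int:
        return self.backbone.num_known_classes


# ---------------------------------------------------------------------------
# video-level aggregation

def forward_frames(frames: np.ndarray, model: SmallCNN,
                   batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame logits (T' x K) and penultimate features (T' x D)."""
    f = np.asarray(frames)
    if f.ndim != 3:
        raise ValueError("expected T x H x W frames")
    logits, feats = [], []
    for i in range(0, f.shape[0], batch_size):
        lo, fe = model.forward(f[i:i + batch_size], train=False)
        logits.append(lo)
        feats.append(fe)
    return np.concatenate(logits), np.concatenate(feats)


def aggregate_logits(frame_logits: np.ndarray) -> np.ndarray:
    """Temporal mean of per-frame logit rows (the video logit vector)."""
    fl = np.asarray(frame_logits, dtype=np.float64)
    if fl.ndim != 2 or fl.shape[0] < 1:
        raise ValueError("frame logits must be a non-empty T' x K matrix")
    return fl.mean(axis=0)


def aggregate_features(frame_features: np.ndarray) -> np.ndarray:
    """Temporal mean of per-frame penultimate features (the embedding)."""
    ff = np.asarray(frame_features, dtype=np.float64)
    if ff.ndim != 2 or ff.shape[0] < 1:
        raise ValueError("frame features must be a non-empty T' x D matrix")
    return ff.mean(axis=0)


def predict_view(video_logits: np.ndarray, outlier_exposure: bool = False) -> int:
    """Argmax over the known-class logits only; the outlier slot (when
    present) is never predicted; ties break toward the lowest index."""
    vl = np.asarray(video_logits, dtype=np.float64)
    known = vl[:-1] if outlier_exposure else vl
    return int(np.argmax(known))


# ---------------------------------------------------------------------------
# sampling and schedule

def make_balanced_sampler(labels: Sequence, rng: np.random.Generator
                          ) -> Iterator[int]:
    """Infinite stream of clip indices: draw a class uniformly, then a clip
    uniformly within that class, with replacement."""
    classes: dict = {}
    for i, lab in enumerate(labels):
        classes.setdefault(lab, []).append(i)
    if not classes:
        raise ValueError("sampler needs at least one labeled clip")
    for lab, idxs in classes.items():
        if not idxs:
            raise ValueError(f"class {lab!r} has no clips")
    keys = sorted(classes.keys(), key=str)
    pools = [np.asarray(classes[k]) for k in keys]

    def _stream():
        while True:
            c = int(rng.integers(len(pools)))
            yield int(pools[c][rng.integers(len(pools[c]))])

    return _stream()


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: the base LR divided by the drop factor once per drop
    epoch reached (epochs are 0-indexed)."""
    drops = sum(1 for d in cfg.lr_drop_epochs if epoch >= d)
    return cfg.lr / (cfg.lr_drop_factor ** drops)


# ---------------------------------------------------------------------------
# training

def _label_to_target(label, class_index: dict) -> int:
    return class_index[label]


def train_classifier(
    train_clips: Sequence[VideoClip],
    val_clips: Sequence[VideoClip] | None,
    train_cfg: TrainConfig,
    backbone_cfg: BackboneConfig,
    preprocess_cfg: PreprocessConfig | None = None,
    preprocessed: Sequence[np.ndarray] | None = None,
) -> TrainedModel:
    """Train the frame classifier with cross-entropy and AdamW.

    Unknown-labeled clips are rejected unless ``backbone_cfg.outlier_exposure``
    is set, in which case clips labeled with the collapsed outlier class are
    trained against the extra logit.  ``preprocessed`` may carry
    already-resized frame stacks (same order as ``train_clips``) to avoid
    recomputing the resize path.
    """
    pp = preprocess_cfg or PreprocessConfig()
    labels = [c.label for c in train_clips]
    known_labels = sorted({l for l in labels if not isinstance(l, str)})
    if any(isinstance(l, str) for l in labels) and not backbone_cfg.outlier_exposure:
        raise ValueError("training set contains unknown-labeled clips; "
                         "enable outlier_exposure to train on them")
    if len(known_labels) != backbone_cfg.num_known_classes:
        raise ValueError(
            f"training set has {len(known_labels)} known classes, backbone "
            f"expects {backbone_cfg.num_known_classes}")
    class_index = {lab: i for i, lab in enumerate(known_labels)}
    if backbone_cfg.outlier_exposure:
        class_index[OUTLIER_LABEL] = backbone_cfg.num_known_classes
        for l in labels:
            if isinstance(l, str) and l != OUTLIER_LABEL:
                raise ValueError(
                    f"outlier-exposed training expects the collapsed label "
                    f"{OUTLIER_LABEL!r}, got {l!r}")

    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(backbone_cfg, seed=int(rng.integers(2**31)))
    opt = AdamW(model.parameters(), lr=train_cfg.lr, betas=train_cfg.betas,
                eps=train_cfg.eps, weight_decay=train_cfg.weight_decay)

    if preprocessed is None:
        preprocessed = [preprocess_clip(c, pp).astype(np.float32) for c in train_clips]
    targets = np.array([_label_to_target(l, class_index) for l in labels])

    if train_cfg.balanced_sampling:
        sampler = make_balanced_sampler(labels, rng)
    else:
        def _seq():
            while True:
                for i in rng.permutation(len(train_clips)):
                    yield int(i)
        sampler = _seq()

    n_iters = math.ceil(len(train_clips) / train_cfg.batch_videos)
    log: list[dict] = []
    for epoch in range(train_cfg.epochs):
        opt.lr = lr_at_epoch(train_cfg, epoch)
        losses, correct, seen = [], 0, 0
        for _ in range(n_iters):
            idxs = [next(sampler) for _ in range(train_cfg.batch_videos)]
            batch_frames = []
            for i in idxs:
                fr = sample_frames(preprocessed[i], "train",
                                   train_cfg.frames_per_video, rng)
                if train_cfg.augment:
                    fr = augment(fr, rng, pp.augment)
                batch_frames.append(fr.astype(np.float32))
            x = np.concatenate(batch_frames)  # (B*F, H, W)
            y_frame = np.repeat(targets[idxs], train_cfg.frames_per_video)
            logits, _ = model.forward(x, train=True)
            loss, dlogits = cross_entropy(logits, y_frame)
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y_frame).sum())
            seen += len(y_frame)
        entry = {"epoch": epoch, "lr": opt.lr,
                 "loss": float(np.mean(losses)),
                 "train_frame_acc": correct / seen,
                 "seed": train_cfg.seed}
        if (train_cfg.val_every and val_clips
                and (epoch + 1) % train_cfg.val_every == 0):
            entry["val_acc"] = _closed_val_accuracy(
                model, val_clips, pp, class_index, backbone_cfg)
        log.append(entry)
    return TrainedModel(model=model, backbone=backbone_cfg,
                        train_config=train_cfg, log=log)


def _closed_val_accuracy(model, clips, pp, class_index, backbone_cfg) -> float:
    """Closed-set accuracy on known-labeled clips with test-mode sampling
    (all frames of each clip)."""
    n_ok = n = 0
    for clip in clips:
        if isinstance(clip.label, str):
            continue
        frames = sample_frames(preprocess_clip(clip, pp), "test")
        fl, _ = forward_frames(frames.astype(np.float32), model)
        pred = predict_view(aggregate_logits(fl), backbone_cfg.outlier_exposure)
        n_ok += int(pred == class_index[clip.label])
        n += 1
    return n_ok / max(n, 1)


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON manifest

def save_checkpoint(tm: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **tm.model.state_dict())
    manifest = {
        "backbone": asdict(tm.backbone),
        "train_config": asdict(tm.train_config) if tm.train_config else None,
        "log": tm.log,
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=1))


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    manifest = json.loads(Path(str(path) + ".json").read_text())
    bb = manifest["backbone"]
    bb_cfg = BackboneConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in bb.items()})
    model = build_model(bb_cfg)
    with np.load(path) as sd:
        model.load_state_dict({k: sd[k] for k in sd.files})
    tc = manifest.get("train_config")
    train_cfg = None
    if tc:
        tc = {k: tuple(v) if isinstance(v, list) else v for k, v in tc.items()}
        train_cfg = TrainConfig(**tc)
    return TrainedModel(model=model, backbone=bb_cfg, train_config=train_cfg,
                        log=manifest.get("log", []))
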