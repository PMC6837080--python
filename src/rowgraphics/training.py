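"""Loss, augmentation, learning-rate schedule, and the training loop.

Both task types (row lines, base keypoints) train the same way: pixel-wise
cross-entropy weighted by inverse class frequency, Adam updates, a stepwise
exponential learning-rate decay, and geometric + photometric augmentation
applied identically to the image (bilinear) and its label mask
(nearest-neighbour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from . import nn
from .annotation import LabelMask, compute_class_weights, read_annotation, rasterize_keypoints, rasterize_lines
from .network import SegmentationNet, save_checkpoint
from .nn.tensor import weighted_cross_entropy_loss
from PIL import Image

__all__ = [
    "TrainConfig",
    "AugSpec",
    "weighted_cross_entropy",
    "sample_aug_params",
    "augment",
    "lr_schedule",
    "train",
    "ManifestDataset",
    "images_to_batch",
]


@dataclass(frozen=True)
class AugSpec:
    """Augmentation ranges; degenerate ranges turn each step off exactly."""

    scale_range: tuple[float, float] = (0.5, 1.5)
    rotation_range: float = 15.0
    hflip_prob: float = 0.5
    brightness_delta: float = 0.2
    saturation_delta: float = 0.2
    crop_size: int = 512

    def validate(self):
        lo, hi = self.scale_range
        if lo > hi or lo <= 0:
            raise ValueError(f"bad scale_range {self.scale_range}")
        if self.rotation_range < 0 or not (0 <= self.hflip_prob <= 1):
            raise ValueError("bad rotation_range or hflip_prob")
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 5
    base_lr: float = 1e-4
    lr_decay_factor: float = 0.94
    lr_decay_interval: int | None = None  # steps; None = one epoch worth of steps
    total_epochs: int | None = 100
    total_iterations: int | None = None  # overrides total_epochs when set
    seed: int = 0
    augmentation: AugSpec | None = None
    class_weights: str | tuple[float, ...] | None = "auto"
    early_stop_miou: float | None = None
    checkpoint_path: str | None = None

    def validate(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")
        if not (0 < self.lr_decay_factor <= 1):
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.total_epochs is None and self.total_iterations is None:
            raise ValueError("set total_epochs or total_iterations")
        if self.augmentation is not None:
            self.augmentation.validate()


def weighted_cross_entropy(scores: nn.Tensor, target, weights) -> nn.Tensor:
    """Class-weighted mean pixel cross-entropy (differentiable).

    With unit weights this is the plain pixel-wise cross-entropy; targets are
    integer class maps of shape (N, H, W) or a single (H, W) mask.
    """
    if hasattr(target, "values"):
        target = target.values
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    if hasattr(weights, "as_array"):
        weights = weights.as_array()
    return weighted_cross_entropy_loss(scores, target, np.asarray(weights, dtype=np.float32))


def lr_schedule(step: int, config: TrainConfig, decay_interval: int | None = None) -> float:
    """Stepwise exponential decay: base_lr * factor ** floor(step / interval)."""
    interval = decay_interval or config.lr_decay_interval or 10_000
    return config.base_lr * config.lr_decay_factor ** (step // interval)


def sample_aug_params(spec: AugSpec, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters from the configured ranges."""
    return {
        "scale": float(rng.uniform(*spec.scale_range)),
        "angle": float(rng.uniform(-spec.rotation_range, spec.rotation_range)),
        "hflip": bool(rng.random() < spec.hflip_prob),
        "brightness": float(rng.uniform(-spec.brightness_delta, spec.brightness_delta)),
        "saturation": float(rng.uniform(-spec.saturation_delta, spec.saturation_delta)),
    }


def _geometric(image, mask_values, scale, angle):
    if scale != 1.0:
        image = sktransform.rescale(
            image, scale, channel_axis=2, order=1, preserve_range=True, anti_aliasing=scale < 1.0
        )
        mask_values = sktransform.rescale(
            mask_values.astype(np.float64), scale, order=0, preserve_range=True, anti_aliasing=False
        )
    if angle != 0.0:
        image = sktransform.rotate(image, angle, order=1, preserve_range=True, mode="constant", cval=0.0)
        mask_values = sktransform.rotate(
            mask_values.astype(np.float64), angle, order=0, preserve_range=True, mode="constant", cval=0.0
        )
    return image, mask_values


def augment(image: np.ndarray, mask: LabelMask, spec: AugSpec, rng: np.random.Generator):
    """Randomly scale, rotate, mirror, photometric-jitter, and crop a pair.

    Geometry is shared between image and mask (bilinear vs nearest); the
    photometric jitter touches the image only. If the transformed image is
    smaller than ``crop_size`` it is padded with background before cropping.
    """
    spec.validate()
    params = sample_aug_params(spec, rng)
    img = np.asarray(image, dtype=np.float64)
    values = mask.values
    img, values = _geometric(img, values, params["scale"], params["angle"])
    values = values.astype(mask.values.dtype)
    if params["hflip"]:
        img = img[:, ::-1]
        values = values[:, ::-1]
    if params["brightness"] != 0.0:
        img = img * (1.0 + params["brightness"])
    if params["saturation"] != 0.0:
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (1.0 + params["saturation"]) * (img - gray)
    img = np.clip(img, 0, 255)

    cs = spec.crop_size
    h, w = values.shape
    if h < cs or w < cs:
        ph, pw = max(cs - h, 0), max(cs - w, 0)
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)))
        values = np.pad(values, ((0, ph), (0, pw)))
        h, w = values.shape
    r0 = int(rng.integers(0, h - cs + 1))
    c0 = int(rng.integers(0, w - cs + 1))
    img = img[r0 : r0 + cs, c0 : c0 + cs]
    values = values[r0 : r0 + cs, c0 : c0 + cs]
    return img.astype(np.uint8), LabelMask(np.ascontiguousarray(values), mask.class_map)


def images_to_batch(images) -> np.ndarray:
    """Stack HxWx3 uint8 images into a normalized (N, 3, H, W) float batch."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2)) / 255.0 - 0.5


class ManifestDataset:
    """Image/mask pairs materialized from a simulate-run manifest TSV."""

    def __init__(self, manifest_path, task: str, line_thickness: int = 5):
        if task not in ("lines", "keypoints"):
            raise ValueError(f"unknown task {task!r}")
        manifest_path = Path(manifest_path)
        root = manifest_path.parent
        self.samples = []
        for line in manifest_path.read_text().splitlines():
            if not line.strip():
                continue
            img_name, ann_name = line.split("\t")
            image = np.asarray(Image.open(root / img_name).convert("RGB"))
            graphic = read_annotation(root / ann_name)
            if task == "lines":
                mask = rasterize_lines(graphic, thickness=line_thickness)
            else:
                mask = rasterize_keypoints(graphic)
            self.samples.append((image, mask, graphic))

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i][:2]

    def graphics(self):
        return [g for _, _, g in self.samples]


def _epoch_steps(n_samples: int, batch_size: int) -> int:
    return math.ceil(n_samples / batch_size)


def train(model: SegmentationNet, dataset, config: TrainConfig):
    """Train a model; returns (model, history).

    ``dataset`` is any sequence of (uint8 image, LabelMask) pairs. History is
    a list of per-epoch records: epoch, mean loss, train mIoU (pooled over
    the epoch's batch predictions), and the learning rate in effect. The
    best-mIoU weights are checkpointed when ``checkpoint_path`` is set, and
    training stops early once ``early_stop_miou`` is reached.
    """
    config.validate()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    n_classes = model.config.n_classes

    if config.class_weights == "auto":
        weights = compute_class_weights([m for _, m in dataset]).as_array()
    elif config.class_weights is None:
        weights = np.ones(n_classes)
    else:
        weights = np.asarray(config.class_weights, dtype=np.float64)
    weights = weights.astype(np.float32)

    steps_per_epoch = _epoch_steps(len(dataset), config.batch_size)
    decay_interval = config.lr_decay_interval or steps_per_epoch
    if config.total_iterations is not None:
        total_epochs = math.ceil(config.total_iterations / steps_per_epoch)
    else:
        total_epochs = config.total_epochs

    optimizer = nn.Adam(model.parameters(), lr=config.base_lr)
    history = []
    best_miou = -1.0
    step = 0
    model.train()
    for epoch in range(total_epochs):
        order = rng.permutation(len(dataset))
        losses = []
        inter = np.zeros(n_classes, dtype=np.int64)
        union = np.zeros(n_classes, dtype=np.int64)
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            ims, masks = [], []
            for i in idx:
                image, mask = dataset[int(i)]
                if config.augmentation is not None:
                    image, mask = augment(image, mask, config.augmentation, rng)
                ims.append(image)
                masks.append(mask.values)
            batch = images_to_batch(ims)
            target = np.stack(masks).astype(np.int64)
            scores = model(nn.Tensor(batch))
            loss = weighted_cross_entropy(scores, target, weights)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"loss became non-finite at epoch {epoch}, step {step} (lr={optimizer.lr:.3g})"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.lr = lr_schedule(step, config, decay_interval)
            optimizer.step()
            step += 1
            losses.append(loss_val)
            pred = np.argmax(scores.data, axis=1)
            for c in range(n_classes):
                p, t = pred == c, target == c
                inter[c] += np.count_nonzero(p & t)
                union[c] += np.count_nonzero(p | t)
        iou = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        miou = float(iou.mean())
        record = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "miou": miou,
            "lr": optimizer.lr,
        }
        history.append(record)
        if miou > best_miou:
            best_miou = miou
            if config.checkpoint_path is not None:
                save_checkpoint(model, config.checkpoint_path)
        if config.early_stop_miou is not None and miou >= config.early_stop_miou:
            break
        if config.total_iterations is not None and step >= config.total_iterations:
            break
    return model, history
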