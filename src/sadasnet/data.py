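"""Datasets: synthetic class-conditional images, HAM10000-style folder
reading, and class balancing with pluggable oversampling.

The synthetic generator is the desk-scale stand-in for dermoscopy data: each
class is a parametric pattern (a Gaussian blob whose position, a sinusoidal
texture whose frequency/orientation, and a colour tilt are all keyed to the
class index) blended into a shared background, plus Gaussian pixel noise.
The ``separability`` knob scales the class-specific component: at 1.0 a small
CNN separates the classes easily, and as it approaches 0 all classes collapse
onto the shared background so accuracy falls to chance.

Balancing follows the majority-class rule: every minority class is raised to
the largest class count.  The oversampler is pluggable — the default applies
label-preserving photometric/geometric transforms to originals; a conditional
generator object (class label -> image) can be plugged into the same seat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageDataset",
    "SyntheticSpec",
    "BalancePlan",
    "generate_synthetic",
    "load_image_folder",
    "balance_plan",
    "balance_dataset",
]


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class ImageDataset:
    """Images (N, H, W, C) uint8, integer labels, class names, provenance flags."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    synthetic: np.ndarray = field(default=None)  # bool per image; False = original

    def __post_init__(self) -> None:
        if self.images.ndim != 4 or self.images.dtype != np.uint8:
            raise DatasetError("images must be uint8 with shape (N, H, W, C)")
        if len(self.images) != len(self.labels):
            raise DatasetError("images/labels length mismatch")
        if len(self.class_names) < 2:
            raise DatasetError("need at least 2 classes")
        if self.synthetic is None:
            object.__setattr__(
                self, "synthetic", np.zeros(len(self.labels), dtype=bool)
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        return ImageDataset(
            self.images[idx], self.labels[idx], self.class_names, self.synthetic[idx]
        )


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 4
    image_size: int = 16
    channels: int = 3
    per_class_counts: tuple[int, ...] | None = None
    noise_sigma: float = 10.0
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.image_size < 1:
            raise DatasetError("need >= 2 classes and a positive image size")
        if self.noise_sigma < 0 or not (0 < self.separability <= 1):
            raise DatasetError("noise_sigma >= 0 and separability in (0, 1] required")
        if self.per_class_counts is not None and len(self.per_class_counts) != self.n_classes:
            raise DatasetError("per_class_counts length must equal n_classes")

    def counts(self) -> tuple[int, ...]:
        return self.per_class_counts or (100,) * self.n_classes


def _class_pattern(k: int, n_classes: int, size: int, channels: int) -> np.ndarray:
    """Deterministic class template in [-1, 1], shape (H, W, C)."""
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    angle = 2 * np.pi * k / n_classes
    cx, cy = 0.5 + 0.3 * np.cos(angle), 0.5 + 0.3 * np.sin(angle)
    blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.15**2)))
    freq = 2.0 + 1.5 * k
    theta = np.pi * k / n_classes
    texture = 0.4 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
    base = blob + texture
    tilt = np.array([np.cos(angle), np.cos(angle + 2), np.cos(angle + 4)])[:channels]
    pattern = base[:, :, None] * (1.0 + 0.3 * tilt)[None, None, :]
    return np.clip(pattern, -1.5, 1.5)


def generate_synthetic(spec: SyntheticSpec) -> ImageDataset:
    """Class-conditional synthetic images; bit-reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    size, ch = spec.image_size, spec.channels
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    background = 40.0 * (xx + yy)[:, :, None] / 2.0  # shared, class-independent
    images, labels = [], []
    for k, count in enumerate(spec.counts()):
        pattern = 90.0 * spec.separability * _class_pattern(k, spec.n_classes, size, ch)
        for _ in range(count):
            noise = rng.normal(0.0, spec.noise_sigma, (size, size, ch))
            img = 110.0 + background + pattern + noise
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(k)
    return ImageDataset(
        np.stack(images),
        np.array(labels, dtype=np.int64),
        tuple(f"class_{k}" for k in range(spec.n_classes)),
    )


def load_image_folder(
    image_dir: str | Path,
    labels_csv: str | Path,
    image_size: int = 224,
    id_column: str = "image_id",
    label_column: str = "dx",
    extensions: Sequence[str] = (".jpg", ".jpeg", ".png"),
) -> ImageDataset:
    """Read an image folder plus a metadata CSV (HAM10000 dialect).

    Labels map to integers in sorted class-name order; images are resized to
    ``image_size`` square with antialiased bilinear resampling.  Unknown
    labels and CSV rows whose image file is absent fail hard.
    """
    image_dir = Path(image_dir)
    meta = pd.read_csv(labels_csv)
    for col in (id_column, label_column):
        if col not in meta.columns:
            raise DatasetError(f"labels CSV missing column {col!r}")
    class_names = tuple(sorted(meta[label_column].astype(str).unique()))
    label_index = {c: i for i, c in enumerate(class_names)}
    images, labels, missing = [], [], []
    for _, row in meta.iterrows():
        image_id = str(row[id_column])
        path = next(
            (p for ext in extensions if (p := image_dir / f"{image_id}{ext}").exists()),
            None,
        )
        if path is None:
            missing.append(image_id)
            continue
        with Image.open(path) as im:
            im = im.convert("RGB").resize(
                (image_size, image_size), Image.Resampling.BILINEAR
            )
            images.append(np.asarray(im, dtype=np.uint8))
        labels.append(label_index[str(row[label_column])])
    if missing:
        raise DatasetError(f"missing image files for ids: {missing}")
    if not images:
        raise DatasetError("no images loaded")
    return ImageDataset(np.stack(images), np.array(labels, dtype=np.int64), class_names)


@dataclass(frozen=True)
class BalancePlan:
    target_per_class: int
    additions: tuple[int, ...]


def balance_plan(class_counts: Sequence[int]) -> BalancePlan:
    """Raise every class to the majority-class count."""
    counts = np.asarray(class_counts, dtype=int)
    if counts.size == 0 or (counts < 0).any():
        raise DatasetError("class counts must be nonempty and nonnegative")
    target = int(counts.max())
    if target == 0:
        raise DatasetError("all class counts are zero")
    return BalancePlan(target, tuple(int(target - c) for c in counts))


def _transform_image(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving augmentation: flips, 90-degree rotations, small
    shifts (edge-padded crops) and intensity jitter."""
    out = img.astype(np.float32)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    if out.shape[0] == out.shape[1] and rng.random() < 0.5:
        out = np.rot90(out, k=int(rng.integers(1, 4)))
    max_shift = max(1, out.shape[0] // 8)
    dy, dx = rng.integers(-max_shift, max_shift + 1, 2)
    out = np.roll(out, (dy, dx), axis=(0, 1))
    out = out * rng.uniform(0.85, 1.15) + rng.uniform(-12, 12)
    return np.clip(out, 0, 255).astype(np.uint8)


def balance_dataset(
    ds: ImageDataset,
    plan: BalancePlan,
    strategy: str | Callable[[int, np.random.Generator], np.ndarray] = "transform-oversample",
    seed: int = 0,
) -> ImageDataset:
    """Append synthetic images per the plan until all classes hit the target.

    ``strategy`` is either ``"transform-oversample"`` (augmented copies of
    class originals) or a conditional generator: a callable mapping
    ``(class_label, rng) -> H x W x C uint8 image`` — the seat a trained
    conditional GAN plugs into.  Appended images are flagged synthetic.
    """
    counts = ds.class_counts()
    if len(plan.additions) != ds.num_classes:
        raise DatasetError("plan does not match the dataset's class count")
    for c, add in enumerate(plan.additions):
        if counts[c] + add != plan.target_per_class:
            raise DatasetError(f"plan inconsistent with dataset counts for class {c}")
    rng = np.random.default_rng(seed)
    new_images, new_labels = [], []
    for c, add in enumerate(plan.additions):
        if add == 0:
            continue
        if callable(strategy):
            new_images.extend(strategy(c, rng) for _ in range(add))
        elif strategy == "transform-oversample":
            pool = np.flatnonzero(ds.labels == c)
            if pool.size == 0:
                raise DatasetError(
                    f"class {c} has no originals to oversample from"
                )
            picks = rng.choice(pool, size=add, replace=True)
            new_images.extend(_transform_image(ds.images[p], rng) for p in picks)
        else:
            raise DatasetError(f"unknown balancing strategy {strategy!r}")
        new_labels.extend([c] * add)
    if not new_images:
        return ds
    return ImageDataset(
        np.concatenate([ds.images, np.stack(new_images)]),
        np.concatenate([ds.labels, np.array(new_labels, dtype=np.int64)]),
        ds.class_names,
        np.concatenate([ds.synthetic, np.ones(len(new_labels), dtype=bool)]),
    )
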