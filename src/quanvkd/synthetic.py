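"""Seeded generator of class-separable grayscale "atrophy phantom" images.

The phantoms stand in for graded dementia MRI slices: each severity class k
is drawn as a centered bright elliptical ring around a dark central cavity,
with both the cavity radius and the ring thickness increasing monotonically
with k — a ventricle-enlargement proxy for atrophy grade.  Class imbalance,
additive Gaussian noise, and rotation/flip/zoom/shift augmentation emulate
the structure of the public dementia MRI collections without any real data.

Everything is reproducible from the spec seed; the noiseless generator is
deterministic per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "AugmentLimits",
    "LabeledDataset",
    "class_counts_from_proportions",
    "generate_dataset",
    "augment",
    "rebalance",
    "save_archive",
    "load_archive",
    "save_png_dir",
]

#: class proportions of the imbalanced 4-class dementia MRI collection the
#: phantoms emulate (mild / moderate / non-dementia / very mild).
DEFAULT_PROPORTIONS = (0.14, 0.01, 0.50, 0.35)
DEFAULT_CLASS_NAMES_4 = ("mild", "moderate", "non_dementia", "very_mild")


@dataclass(frozen=True)
class PhantomSpec:
    """Generator settings for one phantom dataset."""

    image_side: int = 28
    n_classes: int = 4
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side <= 0 or self.image_side % 2 != 0:
            raise ValueError("image_side must be a positive even integer")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        props = tuple(float(p) for p in self.class_proportions)
        object.__setattr__(self, "class_proportions", props)
        if len(props) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if any(p <= 0 for p in props):
            raise ValueError("class proportions must be positive")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {sum(props)!r}, expected 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class AugmentLimits:
    """Uniform sampling bounds for the augmentation transform.

    Defaults are mild, standard magnitudes: rotation +-15 degrees, horizontal
    flip with probability 0.5, zoom +-10%, shift +-10% of the image side.
    Setting every limit to 0 (and flip_p to 0) yields the identity.
    """

    rotation_deg: float = 15.0
    flip_p: float = 0.5
    zoom_frac: float = 0.10
    shift_frac: float = 0.10


@dataclass
class LabeledDataset:
    """Grayscale images in [0, 1] with integer class labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        k = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError(f"labels must lie in [0, {k})")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_count(self, k: int) -> int:
        return int(np.sum(self.labels == k))

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.images[indices], self.labels[indices],
                              list(self.class_names))


def class_counts_from_proportions(proportions: tuple[float, ...], n_total: int) -> np.ndarray:
    """Floor-rounded per-class counts; the remainder goes to the largest class."""
    props = np.asarray(proportions, dtype=float)
    counts = np.floor(props * n_total).astype(int)
    remainder = n_total - int(counts.sum())
    counts[int(np.argmax(props))] += remainder
    return counts


def _phantom_template(side: int, k: int, n_classes: int) -> np.ndarray:
    """Noiseless class-k phantom: brain disc + bright ring + growing cavity."""
    c = (side - 1) / 2.0
    y, x = np.mgrid[0:side, 0:side]
    # mildly elliptical radius (axis ratio 0.88) so orientation matters
    r = np.sqrt(((x - c) / 1.0) ** 2 + ((y - c) / 0.88) ** 2)
    scale = side / 28.0
    grade = k / (n_classes - 1)
    r_in = (1.0 + 3.0 * grade) * scale
    r_out = r_in + (1.6 + 0.9 * grade) * scale
    r_brain = 6.8 * scale

    img = np.zeros((side, side), dtype=float)
    img[r <= r_brain] = 0.35          # faint parenchyma disc
    img[(r >= r_in) & (r <= r_out)] = 0.90   # bright ring (its radius codes grade)
    img[r < r_in] = 0.08              # dark central cavity ("ventricle")
    return img


def generate_dataset(spec: PhantomSpec, n_total: int) -> LabeledDataset:
    """Draw ``n_total`` phantoms with floor-rounded class proportions.

    Class identity is encoded purely by the deterministic ring geometry;
    additive Gaussian noise (sd ``spec.noise_sd``) is clipped to [0, 1].
    """
    if n_total < spec.n_classes:
        raise ValueError(f"n_total {n_total} < n_classes {spec.n_classes}")
    counts = class_counts_from_proportions(spec.class_proportions, n_total)
    rng = np.random.default_rng(spec.seed)
    templates = [_phantom_template(spec.image_side, k, spec.n_classes)
                 for k in range(spec.n_classes)]
    images, labels = [], []
    for k, n_k in enumerate(counts):
        base = templates[k]
        noise = rng.normal(0.0, spec.noise_sd, size=(n_k, *base.shape)) \
            if spec.noise_sd > 0 else np.zeros((n_k, *base.shape))
        images.append(np.clip(base[None, :, :] + noise, 0.0, 1.0))
        labels.append(np.full(n_k, k, dtype=int))
    names = list(DEFAULT_CLASS_NAMES_4) if spec.n_classes == 4 \
        else [f"class_{k}" for k in range(spec.n_classes)]
    return LabeledDataset(np.concatenate(images), np.concatenate(labels), names)


def augment(image: np.ndarray, rng: np.random.Generator,
            limits: AugmentLimits = AugmentLimits()) -> np.ndarray:
    """One random rotation / flip / zoom / shift draw, clipped to [0, 1].

    The transform parameters are sampled uniformly within ``limits`` from
    ``rng``; with all limits at zero the output equals the input exactly.
    """
    image = np.asarray(image, dtype=float)
    side = image.shape[0]

    angle = rng.uniform(-limits.rotation_deg, limits.rotation_deg)
    do_flip = rng.uniform() < limits.flip_p
    zoom = 1.0 + rng.uniform(-limits.zoom_frac, limits.zoom_frac)
    shift_y = rng.uniform(-limits.shift_frac, limits.shift_frac) * side
    shift_x = rng.uniform(-limits.shift_frac, limits.shift_frac) * side

    out = image
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    if do_flip:
        out = out[:, ::-1]
    if zoom != 1.0:
        c = (side - 1) / 2.0
        matrix = np.eye(2) / zoom
        offset = c * (1.0 - 1.0 / zoom)
        out = ndimage.affine_transform(out, matrix, offset=(offset, offset),
                                       order=1, mode="nearest")
    if shift_y != 0.0 or shift_x != 0.0:
        out = ndimage.shift(out, (shift_y, shift_x), order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def rebalance(dataset: LabeledDataset, target_counts,
              rng: np.random.Generator,
              limits: AugmentLimits = AugmentLimits()) -> LabeledDataset:
    """Resample every class to its target count.

    Deficit classes are topped up with augmented copies of their own members
    (drawn with replacement); surplus classes are subsampled without
    replacement.  Labels are conserved.
    """
    target_counts = np.asarray(target_counts, dtype=int)
    if len(target_counts) != dataset.n_classes:
        raise ValueError("one target count per class required")
    if np.any(target_counts < 0):
        raise ValueError("target counts must be nonnegative")

    images, labels = [], []
    for k, target in enumerate(target_counts):
        member_idx = np.flatnonzero(dataset.labels == k)
        if target > 0 and len(member_idx) == 0:
            raise ValueError(f"class {k} has no members but target {target}")
        if target <= len(member_idx):
            keep = rng.choice(member_idx, size=target, replace=False)
            images.append(dataset.images[keep])
        else:
            images.append(dataset.images[member_idx])
            n_extra = target - len(member_idx)
            sources = rng.choice(member_idx, size=n_extra, replace=True)
            extra = np.stack([augment(dataset.images[i], rng, limits) for i in sources])
            images.append(extra)
        labels.append(np.full(target, k, dtype=int))
    return LabeledDataset(np.concatenate(images), np.concatenate(labels),
                          list(dataset.class_names))


# -- persistence -------------------------------------------------------------

def save_archive(dataset: LabeledDataset, path: str | Path) -> None:
    """Single compressed array archive (images, labels, class names)."""
    np.savez_compressed(Path(path), images=dataset.images, labels=dataset.labels,
                        class_names=np.asarray(dataset.class_names))


def load_archive(path: str | Path) -> LabeledDataset:
    with np.load(Path(path), allow_pickle=False) as z:
        return LabeledDataset(z["images"], z["labels"],
                              [str(n) for n in z["class_names"]])


def save_png_dir(dataset: LabeledDataset, root: str | Path) -> None:
    """Directory-per-class PNG layout (the Kaggle-style on-disk form)."""
    from PIL import Image

    root = Path(root)
    for k, name in enumerate(dataset.class_names):
        (root / name).mkdir(parents=True, exist_ok=True)
    digits = max(4, len(str(len(dataset))))
    for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        u8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        out = root / dataset.class_names[lab] / f"img_{i:0{digits}d}.png"
        Image.fromarray(u8, mode="L").save(out)
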