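"""Dataset readers, normalization, augmentation (incl. CutMix) and a
synthetic frequency-structured image generator.

The synthetic generator makes the whole stack testable without downloads:
each class is defined by a smooth radial bump (low spatial frequency, class-
specific position and radius) plus a sinusoidal grating (high spatial
frequency, class-specific frequency and orientation), with additive Gaussian
noise. Class information is deliberately split across frequency bands so
that both streams of the frequency-decomposition module are informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

# ImageNet channel statistics used to normalize all inputs
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

SPLITS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_medmnist(path, split):
    """Read one split of a MedMNIST-style npz archive.

    Returns (images, labels): images N×H×W×3 uint8 (grayscale replicated to
    three channels), labels 1-D int64.
    """
    if split not in SPLITS:
        raise ValueError(f"split must be one of {SPLITS}, got {split!r}")
    with np.load(path) as archive:
        img_key, lab_key = f"{split}_images", f"{split}_labels"
        for key in (img_key, lab_key):
            if key not in archive.files:
                raise KeyError(f"archive {path} is missing key {key!r}")
        images = archive[img_key]
        labels = archive[lab_key]
    if images.ndim == 3:
        images = np.repeat(images[..., None], 3, axis=-1)
    elif images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"images must be N×H×W or N×H×W×3, got shape {images.shape}")
    labels = np.asarray(labels).reshape(-1).astype(np.int64)
    if len(labels) != len(images):
        raise ValueError("label/image count mismatch")
    return images.astype(np.uint8), labels


def read_image_folder(root):
    """`root/<class_name>/*.png|jpg` layout; class index = sorted folder order."""
    root = Path(root)
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    for idx, name in enumerate(classes):
        for f in sorted((root / name).iterdir()):
            if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                arr = np.asarray(Image.open(f).convert("RGB"), dtype=np.uint8)
                images.append(arr)
                labels.append(idx)
    return np.stack(images), np.asarray(labels, dtype=np.int64), classes


def write_medmnist(path, splits):
    """Export `{split: (images, labels)}` to the npz archive layout."""
    payload = {}
    for split, (images, labels) in splits.items():
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        payload[f"{split}_images"] = np.asarray(images, dtype=np.uint8)
        payload[f"{split}_labels"] = np.asarray(labels, dtype=np.int64).reshape(-1, 1)
    np.savez_compressed(path, **payload)


# ---------------------------------------------------------------------------
# normalization / resize
# ---------------------------------------------------------------------------

def normalize(images):
    """uint8 or [0,1]-float N×H×W×3 (or H×W×3) → normalized N×3×H×W float32."""
    arr = np.asarray(images)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.shape[-1] != 3:
        raise ValueError(f"expected 3 channels last, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    arr = (arr.astype(np.float32) - IMAGENET_MEAN) / IMAGENET_STD
    arr = np.ascontiguousarray(arr.transpose(0, 3, 1, 2))
    return arr[0] if single else arr


def denormalize(batch):
    """Inverse of normalize: N×3×H×W float32 → N×H×W×3 floats in [0,1]."""
    arr = np.asarray(batch)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    arr = arr.transpose(0, 2, 3, 1) * IMAGENET_STD + IMAGENET_MEAN
    return arr[0] if single else arr


def resize(images, target_size):
    """Bilinear resize of N×H×W×3 (or H×W×3) images to target_size²."""
    arr = np.asarray(images)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.shape[1] == target_size and arr.shape[2] == target_size:
        return arr[0] if single else arr
    was_uint8 = arr.dtype == np.uint8
    scaled = np.empty((arr.shape[0], target_size, target_size, 3), dtype=np.float32)
    for i, img in enumerate(arr):
        scaled[i] = sktransform.resize(
            img.astype(np.float32) / (255.0 if was_uint8 else 1.0),
            (target_size, target_size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True)
    scaled = np.clip(scaled, 0.0, 1.0)
    if was_uint8:
        return (scaled * 255.0 + 0.5).astype(np.uint8)
    return scaled[0] if single else scaled


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    """Training-time augmentation stack. Applied to the training split only."""

    hflip_prob: float = 0.5
    translate_frac: float = 0.10
    perspective_prob: float = 0.5
    perspective_scale: float = 0.2
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.02
    blur_sigma: tuple = (0.1, 1.0)
    blur_prob: float = 0.5
    erase_prob: float = 0.5
    erase_area: tuple = (0.02, 0.2)
    cutmix_prob: float = 0.5
    cutmix_alpha: float = 1.0
    mode: str = "normal"  # "normal" or "cutmix" (ablation arms)

    def __post_init__(self):
        for name in ("hflip_prob", "perspective_prob", "blur_prob", "erase_prob", "cutmix_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.mode not in ("normal", "cutmix"):
            raise ValueError("mode must be 'normal' or 'cutmix'")


def _rgb_to_hsv(img):
    from skimage.color import rgb2hsv
    return rgb2hsv(img)


def _hsv_to_rgb(img):
    from skimage.color import hsv2rgb
    return hsv2rgb(img)


def augment(image, cfg: AugmentationConfig, rng: np.random.Generator):
    """Apply the geometric/photometric stack to one H×W×3 image in [0,1].

    Order: horizontal flip, random affine translation, random perspective,
    color jitter (brightness/contrast/saturation/hue), Gaussian blur, random
    erasing. Fully determined by the rng state.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    H, W = img.shape[:2]

    if rng.random() < cfg.hflip_prob:
        img = img[:, ::-1].copy()

    if cfg.translate_frac > 0:
        dy = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * H
        dx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * W
        img = ndimage.shift(img, (dy, dx, 0), order=1, mode="nearest")

    if rng.random() < cfg.perspective_prob and cfg.perspective_scale > 0:
        d = cfg.perspective_scale
        src = np.array([[0, 0], [W, 0], [W, H], [0, H]], dtype=np.float64)
        jitter = rng.uniform(-d, d, (4, 2)) * [W, H]
        tf = sktransform.ProjectiveTransform.from_estimate(src + jitter, src)
        if tf:
            img = sktransform.warp(img, tf.inverse, order=1, mode="edge",
                                   preserve_range=True).astype(np.float32)

    if cfg.brightness > 0:
        img = img * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if cfg.contrast > 0:
        f = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
        img = (img - img.mean()) * f + img.mean()
    img = np.clip(img, 0.0, 1.0)
    if cfg.saturation > 0 or cfg.hue > 0:
        hsv = _rgb_to_hsv(img)
        if cfg.saturation > 0:
            hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(1 - cfg.saturation, 1 + cfg.saturation), 0, 1)
        if cfg.hue > 0:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue, cfg.hue)) % 1.0
        img = _hsv_to_rgb(hsv).astype(np.float32)

    if rng.random() < cfg.blur_prob:
        sigma = rng.uniform(*cfg.blur_sigma)
        img = ndimage.gaussian_filter(img, (sigma, sigma, 0))

    if rng.random() < cfg.erase_prob:
        area = rng.uniform(*cfg.erase_area) * H * W
        aspect = rng.uniform(0.3, 3.3)
        eh = max(1, min(H, int(round(np.sqrt(area * aspect)))))
        ew = max(1, min(W, int(round(np.sqrt(area / aspect)))))
        top = rng.integers(0, H - eh + 1)
        left = rng.integers(0, W - ew + 1)
        img[top:top + eh, left:left + ew] = rng.random((eh, ew, 3), dtype=np.float32)

    return np.clip(img, 0.0, 1.0)


def cutmix(images, labels, cfg: AugmentationConfig, rng: np.random.Generator, lam=None):
    """CutMix a batch: paste a random box from a shuffled partner image.

    images: B×C×H×W (any float layout with spatial last two axes).
    Returns (mixed_images, labels_a, labels_b, lam) where lam is recomputed
    from the clipped box area. With probability 1−cutmix_prob (or batch size
    < 2) the batch is returned unchanged with lam = 1. ``lam`` can be forced
    for analysis.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    B = images.shape[0]
    H, W = images.shape[-2], images.shape[-1]
    if B < 2 or (lam is None and rng.random() >= cfg.cutmix_prob):
        return images, labels, labels.copy(), 1.0
    if lam is None:
        lam = float(rng.beta(cfg.cutmix_alpha, cfg.cutmix_alpha))
    perm = rng.permutation(B)
    cut = np.sqrt(1.0 - lam)
    bh, bw = int(np.round(H * cut)), int(np.round(W * cut))
    cy, cx = int(rng.integers(0, H)), int(rng.integers(0, W))
    y1, y2 = np.clip(cy - bh // 2, 0, H), np.clip(cy - bh // 2 + bh, 0, H)
    x1, x2 = np.clip(cx - bw // 2, 0, W), np.clip(cx - bw // 2 + bw, 0, W)
    mixed = images.copy()
    mixed[..., y1:y2, x1:x2] = images[perm][..., y1:y2, x1:x2]
    lam_adjusted = 1.0 - (y2 - y1) * (x2 - x1) / (H * W)
    return mixed, labels, labels[perm], float(lam_adjusted)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Class-separable two-frequency image dataset description.

    Per class: a radial Gaussian bump (low-frequency shape; position/radius)
    plus a sinusoidal grating (high-frequency texture; cycles/orientation).
    Defaults give four well-separated classes at 32×32 with mild noise.
    """

    num_classes: int = 4
    samples_per_class: int = 50
    image_size: int = 32
    blob_positions: tuple | None = None   # per-class (y, x) in [0,1] coords
    blob_radii: tuple | None = None       # per-class radius in [0,1] units
    grating_freqs: tuple | None = None    # per-class cycles across the image
    grating_orients: tuple | None = None  # per-class orientation (radians)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        K = self.num_classes
        if K < 2:
            raise ValueError("need at least two classes")
        if self.blob_positions is None:
            angles = 2 * np.pi * np.arange(K) / K
            self.blob_positions = tuple(
                (0.5 + 0.25 * np.sin(a), 0.5 + 0.25 * np.cos(a)) for a in angles)
        if self.blob_radii is None:
            self.blob_radii = tuple(0.15 + 0.1 * (c % 2) for c in range(K))
        if self.grating_freqs is None:
            self.grating_freqs = tuple(6 + 3 * c for c in range(K))
        if self.grating_orients is None:
            self.grating_orients = tuple(np.pi * c / K for c in range(K))
        params = list(zip(self.blob_positions, self.blob_radii,
                          self.grating_freqs, self.grating_orients))
        if len(set(map(str, params))) != K:
            raise ValueError("class-conditional parameters must be pairwise distinct")


def synth_generate(spec: SyntheticSpec):
    """Deterministically render the dataset; returns (images uint8 N×S×S×3, labels)."""
    rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    yy, xx = np.mgrid[0:S, 0:S] / (S - 1)
    images, labels = [], []
    for c in range(spec.num_classes):
        (by, bx), r = spec.blob_positions[c], spec.blob_radii[c]
        freq, theta = spec.grating_freqs[c], spec.grating_orients[c]
        for _ in range(spec.samples_per_class):
            jy = by + rng.normal(0, 0.02)
            jx = bx + rng.normal(0, 0.02)
            blob = np.exp(-(((yy - jy) ** 2 + (xx - jx) ** 2) / (2 * r ** 2)))
            phase = rng.uniform(0, 2 * np.pi)
            grating = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
            img = 0.55 * blob + 0.25 * (grating * 0.5 + 0.5)
            img = img + rng.normal(0, spec.noise_sigma, (S, S))
            images.append(np.clip(img, 0, 1))
            labels.append(c)
    order = np.random.default_rng(spec.seed + 1).permutation(len(images))
    arr = (np.asarray(images, dtype=np.float32)[order] * 255 + 0.5).astype(np.uint8)
    arr = np.repeat(arr[..., None], 3, axis=-1)
    return arr, np.asarray(labels, dtype=np.int64)[order]


def synth_train_test(spec: SyntheticSpec, test_fraction=1 / 3):
    """Split a synthetic dataset into train/test with balanced classes."""
    images, labels = synth_generate(spec)
    n_test_per_class = int(round(spec.samples_per_class * test_fraction))
    test_idx = []
    for c in range(spec.num_classes):
        test_idx.extend(np.where(labels == c)[0][:n_test_per_class])
    mask = np.zeros(len(labels), dtype=bool)
    mask[test_idx] = True
    return (images[~mask], labels[~mask]), (images[mask], labels[mask])
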