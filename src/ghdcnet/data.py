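"""Dataset I/O, resizing, splitting, and synthetic lesion-image generation.

Real data follow the image/mask folder layout used by the public polyp
segmentation datasets (Kvasir-SEG: resized to 256x320; CVC-ClinicDB: 288x384):
``images/*.png|jpg`` with a same-named mask in ``masks/``.  The synthetic
generator emulates the single-bright-lesion structure of such images — one or
more textured, irregular elliptical blobs on a darker textured background,
with an exact ground-truth mask — so that the whole pipeline is testable
without downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as _skdraw

__all__ = [
    "SegSample",
    "SplitPlan",
    "SynthConfig",
    "PRESETS",
    "load_dataset",
    "save_dataset",
    "resize_sample",
    "split_dataset",
    "largest_remainder_counts",
    "generate_synthetic",
    "write_split_manifest",
]

PRESETS = {"kvasir": (256, 320), "cvc": (288, 384)}

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass(frozen=True)
class SegSample:
    """One image/mask pair: HxWx3 uint8 image, HxW {0,1} mask, string id."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"{self.id}: image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"{self.id}: mask shape {self.mask.shape} does not match "
                f"image {self.image.shape[:2]}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError(f"{self.id}: mask must be binary 0/1")


@dataclass(frozen=True)
class SplitPlan:
    """Seeded 7:2:1 train/test/validation split by largest-remainder apportionment."""

    ratios: tuple[int, int, int] = (7, 2, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic lesion generator.

    Defaults draw 1-2 bright reddish blobs of radius 6-18 px on a darker
    textured 64x64 background with ~90 grey-level foreground/background
    contrast, mild boundary irregularity and occasional specular highlights —
    a deliberately easy stand-in for endoscopic lesion appearance.
    """

    image_size: tuple[int, int] = (64, 64)
    blob_count: tuple[int, int] = (1, 2)
    blob_radius: tuple[float, float] = (6.0, 18.0)
    irregularity: float = 0.25
    fg_mean: float = 175.0
    bg_mean: float = 85.0
    texture_scale: float = 12.0
    specular_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blob_radius[0] < 2:
            raise ValueError("blob radii must be >= 2 px")
        h, w = self.image_size
        if self.blob_radius[1] * 2 >= min(h, w):
            raise ValueError(
                f"largest blob (diameter {self.blob_radius[1] * 2:g}) does not fit "
                f"in a {h}x{w} image"
            )
        for v in (self.fg_mean, self.bg_mean):
            if not 0 <= v <= 255:
                raise ValueError("intensity means must be within 8-bit range")


def _binarize(mask: np.ndarray) -> np.ndarray:
    return (mask != 0).astype(np.uint8)


def load_dataset(image_dir, mask_dir) -> list[SegSample]:
    """Load image/mask pairs in deterministic lexicographic order of image stems.

    Every image must have a same-stem mask; masks binarize as nonzero -> 1.
    Errors name the offending file.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    for d in (image_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"not a directory: {d}")
    images = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    masks_by_stem: dict[str, Path] = {}
    for p in sorted(mask_dir.iterdir()):
        if p.suffix.lower() in _IMAGE_SUFFIXES:
            masks_by_stem.setdefault(p.stem, p)
    samples = []
    for img_path in images:
        mask_path = masks_by_stem.get(img_path.stem)
        if mask_path is None:
            raise FileNotFoundError(f"no mask found for image {img_path}")
        try:
            image = np.asarray(Image.open(img_path).convert("RGB"))
            mask = np.asarray(Image.open(mask_path).convert("L"))
        except Exception as exc:  # unreadable file, named
            raise OSError(f"failed to read {img_path} / {mask_path}: {exc}") from exc
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"{img_path.name}: mask {mask_path.name} has shape {mask.shape}, "
                f"image has {image.shape[:2]}"
            )
        samples.append(SegSample(image=image, mask=_binarize(mask), id=img_path.stem))
    return samples


def save_dataset(samples: Sequence[SegSample], out_dir) -> None:
    """Write samples as PNG (lossless, so masks round-trip exactly)."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(out_dir / "images" / f"{s.id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out_dir / "masks" / f"{s.id}.png")


def resize_sample(sample: SegSample, target: tuple[int, int]) -> SegSample:
    """Resize to (H, W): bilinear for the image, nearest for the mask (stays binary)."""
    h, w = target
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    image = np.asarray(Image.fromarray(sample.image).resize((w, h), Image.BILINEAR))
    mask = np.asarray(Image.fromarray(sample.mask).resize((w, h), Image.NEAREST))
    return SegSample(image=image, mask=_binarize(mask), id=sample.id)


def largest_remainder_counts(n: int, ratios: Sequence[int]) -> tuple[int, ...]:
    """Apportion n into integer counts proportional to ratios (largest remainder;
    ties broken toward earlier ratio entries)."""
    total = sum(ratios)
    counts = [n * r // total for r in ratios]
    remainders = [n * r % total for r in ratios]  # integer arithmetic: no float ties
    order = sorted(range(len(ratios)), key=lambda i: (-remainders[i], i))
    for i in range(n - sum(counts)):
        counts[order[i]] += 1
    return tuple(counts)


def split_dataset(
    samples: Sequence[SegSample], plan: SplitPlan
) -> tuple[list[SegSample], list[SegSample], list[SegSample]]:
    """Seeded shuffle then largest-remainder 7:2:1 partition into (train, test, val)."""
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples to split, got {len(samples)}")
    counts = largest_remainder_counts(len(samples), plan.ratios)
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(samples))
    shuffled = [samples[i] for i in order]
    a, b = counts[0], counts[0] + counts[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def write_split_manifest(splits, path) -> None:
    """CSV manifest (id, split) for a (train, test, val) triple."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "split"])
        for label, part in zip(("train", "test", "val"), splits):
            for s in part:
                writer.writerow([s.id, label])


def _smooth_noise(rng: np.random.Generator, shape, sigma: float, amplitude: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(field_).max()
    return field_ * (amplitude / peak) if peak > 0 else field_


def _blob_mask(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Rasterize one radial-harmonic-perturbed ellipse as a filled polygon mask."""
    h, w = cfg.image_size
    r_lo, r_hi = cfg.blob_radius
    a = rng.uniform(r_lo, r_hi)
    b = rng.uniform(r_lo, r_hi)
    rmax = max(a, b) * (1 + cfg.irregularity)
    cy = rng.uniform(rmax + 1, h - rmax - 1)
    cx = rng.uniform(rmax + 1, w - rmax - 1)
    rot = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    # low-order harmonics perturb the radius -> irregular but smooth boundary
    pert = np.zeros_like(theta)
    for harmonic in (2, 3, 5):
        pert += rng.uniform(0, cfg.irregularity / 3) * np.cos(
            harmonic * theta + rng.uniform(0, 2 * np.pi)
        )
    radius = 1.0 + pert
    ex = a * radius * np.cos(theta)
    ey = b * radius * np.sin(theta)
    rows = cy + ex * np.sin(rot) + ey * np.cos(rot)
    cols = cx + ex * np.cos(rot) - ey * np.sin(rot)
    rr, cc = _skdraw.polygon(rows, cols, shape=(h, w))
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def generate_synthetic(config: SynthConfig, n: int) -> list[SegSample]:
    """Generate ``n`` seeded image/mask pairs with bright irregular lesion blobs.

    Background: reddish-brown base with a smooth illumination field and fine
    texture noise.  Foreground: brighter pinkish blobs, same texture treatment,
    plus occasional small specular highlights.  Masks are exact by
    construction and always non-empty.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    samples = []
    # fixed channel tints around the configured grey-level means (endoscopy-like)
    bg_tint = np.array([1.10, 0.80, 0.70])
    fg_tint = np.array([1.15, 0.85, 0.75])
    for i in range(n):
        mask = np.zeros((h, w), dtype=np.uint8)
        count = int(rng.integers(config.blob_count[0], config.blob_count[1] + 1))
        for _ in range(count):
            mask |= _blob_mask(rng, config)
        illum = _smooth_noise(rng, (h, w), sigma=min(h, w) / 4, amplitude=0.12)
        texture = rng.normal(0.0, config.texture_scale, size=(h, w))
        base = np.where(mask == 1, config.fg_mean, config.bg_mean).astype(np.float64)
        grey = base * (1.0 + illum) + ndimage.gaussian_filter(texture, 0.8)
        tint = np.where(mask[..., None] == 1, fg_tint, bg_tint)
        image = grey[..., None] * tint
        if rng.uniform() < config.specular_prob and mask.any():
            ys, xs = np.nonzero(mask)
            j = rng.integers(len(ys))
            spot = np.zeros((h, w))
            spot[ys[j], xs[j]] = 1.0
            image += ndimage.gaussian_filter(spot, 1.5)[..., None] * 900.0
        image = np.clip(image, 0, 255).astype(np.uint8)
        samples.append(SegSample(image=image, mask=mask, id=f"synth_{config.seed}_{i:05d}"))
    return samples
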