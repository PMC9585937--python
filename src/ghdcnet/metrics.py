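"""Segmentation losses and evaluation metrics for binary lesion masks.

Training loss: binary cross-entropy plus the soft Dice loss.  Evaluation:
Dice overlap, average symmetric surface distance (ASSD, in pixels) and the
two-class mean intersection-over-union (mIoU).  Conventions fixed here and
exercised by the tests:

* empty-vs-empty masks score perfectly (Dice 1, mIoU class terms 0/0 -> 1);
* soft Dice uses an additive smoothing epsilon of 1e-6;
* cross-entropy clips probabilities to [1e-7, 1 - 1e-7], mean reduction by
  default;
* ASSD boundaries are foreground pixels with at least one background
  4-neighbour, with the image border counting as background; distances are
  Euclidean between pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "dice",
    "soft_dice_loss",
    "bce_loss",
    "combined_loss",
    "assd",
    "miou",
    "boundary_points",
    "MetricSummary",
    "summarize",
]

SOFT_DICE_EPS = 1e-6
BCE_CLIP_EPS = 1e-7

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _as_mask(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(bool)

def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(pred, truth) -> float:
    """Dice overlap 2|S∩G| / (|S|+|G|); two empty masks score 1.0."""
    s = _as_mask(pred, "pred")
    g = _as_mask(truth, "truth")
    _check_shapes(s, g)
    denom = int(s.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((s & g).sum()) / denom


def soft_dice_loss(pred, truth) -> float:
    """Soft Dice loss 1 - 2 Σ p·t / (Σ p + Σ t) on probabilities, smoothed by 1e-6."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    _check_shapes(p, t)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    num = 2.0 * float((p * t).sum()) + SOFT_DICE_EPS
    den = float(p.sum()) + float(t.sum()) + SOFT_DICE_EPS
    return 1.0 - num / den


def bce_loss(pred, truth, reduction: str = "mean") -> float:
    """Binary cross-entropy on probabilities, clipped away from {0,1} by 1e-7."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    _check_shapes(p, t)
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    p = np.clip(p, BCE_CLIP_EPS, 1.0 - BCE_CLIP_EPS)
    ll = t * np.log(p) + (1.0 - t) * np.log(1.0 - p)
    return float(-ll.mean()) if reduction == "mean" else float(-ll.sum())


def combined_loss(pred, truth, reduction: str = "mean") -> float:
    """Training objective: binary cross-entropy plus soft Dice loss."""
    return bce_loss(pred, truth, reduction=reduction) + soft_dice_loss(pred, truth)


def boundary_points(mask) -> np.ndarray:
    """(n, 2) row/col coordinates of boundary pixels of a binary mask.

    A boundary pixel is a foreground pixel with at least one background pixel
    among its 4-neighbours; pixels on the image border are boundary (the
    outside counts as background).
    """
    m = _as_mask(mask, "mask")
    interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(m & ~interior)


def assd(pred, truth, empty: str = "raise") -> float:
    """Average symmetric surface distance between mask boundaries, in pixels.

    ``(Σ_{m∈Pa} d(m, Pb) + Σ_{n∈Pb} d(n, Pa)) / (|Pa| + |Pb|)`` with Euclidean
    point-to-set distances, computed with distance transforms.  An empty mask
    has no boundary: ``empty='raise'`` raises, ``empty='worst'`` returns the
    image diagonal as a worst-case sentinel (never a silent 0).
    """
    s = _as_mask(pred, "pred")
    g = _as_mask(truth, "truth")
    _check_shapes(s, g)
    if empty not in ("raise", "worst"):
        raise ValueError(f"empty must be 'raise' or 'worst', got {empty!r}")
    pa = boundary_points(s)
    pb = boundary_points(g)
    if len(pa) == 0 or len(pb) == 0:
        if len(pa) == 0 and len(pb) == 0:
            return 0.0  # both empty: boundaries agree (vacuously)
        if empty == "raise":
            raise ValueError("ASSD undefined: one mask is empty")
        return float(np.hypot(*s.shape))
    # distance_transform_edt gives each pixel's distance to the nearest zero,
    # so zero-out the boundary of the *other* mask and sample at our boundary.
    dist_to_b = ndimage.distance_transform_edt(~_points_image(pb, s.shape))
    dist_to_a = ndimage.distance_transform_edt(~_points_image(pa, s.shape))
    total = dist_to_b[pa[:, 0], pa[:, 1]].sum() + dist_to_a[pb[:, 0], pb[:, 1]].sum()
    return float(total / (len(pa) + len(pb)))


def _points_image(points: np.ndarray, shape) -> np.ndarray:
    img = np.zeros(shape, dtype=bool)
    img[points[:, 0], points[:, 1]] = True
    return img


def miou(pred, truth) -> float:
    """Two-class mean IoU: ½[TP/(FN+FP+TP) + TN/(FP+FN+TN)], empty classes 0/0 -> 1."""
    s = _as_mask(pred, "pred")
    g = _as_mask(truth, "truth")
    _check_shapes(s, g)
    tp = int((s & g).sum())
    fp = int((s & ~g).sum())
    fn = int((~s & g).sum())
    tn = int((~s & ~g).sum())
    fg = tp / (fn + fp + tp) if (fn + fp + tp) > 0 else 1.0
    bg = tn / (fp + fn + tn) if (fp + fn + tn) > 0 else 1.0
    return 0.5 * (fg + bg)


@dataclass(frozen=True)
class MetricSummary:
    """Mean and population standard deviation of a per-image metric."""

    mean: float
    std: float
    n: int

    def __str__(self) -> str:  # "94.45 (±1.48)" style, caller scales to %
        return f"{self.mean:.4f} (±{self.std:.4f})"


def summarize(values) -> MetricSummary:
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize zero values")
    return MetricSummary(mean=float(v.mean()), std=float(v.std()), n=int(v.size))
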