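"""Stage-1 detection: per-vertebra instance masks and their centers of gravity.

The detector backend is pluggable: any callable mapping a 2-D grayscale
image to a list of :class:`InstanceMask` qualifies (a trained Mask R-CNN
would be one such backend).  The reference backend shipped here is a
deterministic Otsu-threshold + connected-component labeler, adequate for
synthetic phantoms where bone is brighter than background.

Also hosts the training-time augmentation operators (edge enhancement,
noise addition, resizing, contrast adjustment, rotation) as reusable,
seedable image transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage import filters as _filters
from skimage import measure as _measure
from skimage import transform as _transform

from .errors import BackendError, ValidationError

__all__ = [
    "InstanceMask",
    "CenterPoint",
    "segment_vertebrae",
    "threshold_backend",
    "mask_centroid",
    "augment_image",
    "AUGMENT_KINDS",
]


@dataclass(frozen=True)
class InstanceMask:
    """One detected vertebral body: a binary mask aligned to the input image."""

    mask: np.ndarray
    score: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValidationError("instance mask must be a 2-D raster")
        if not m.any():
            raise ValidationError("instance mask must be nonempty")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class CenterPoint:
    """A vertebral center in image pixel coordinates (origin top-left,
    x rightward, y downward/caudal)."""

    x: float
    y: float
    source_mask_index: int = -1

    def __iter__(self):
        yield self.x
        yield self.y


def threshold_backend(
    image: np.ndarray, min_area: int = 64
) -> list[InstanceMask]:
    """Reference detector: global Otsu threshold + connected components.

    Deterministic; components smaller than ``min_area`` pixels are dropped;
    masks are returned sorted by centroid y (cranial to caudal).  Confuser
    structures brighter than background produce extra masks by design —
    rejecting them is the job of the downstream spinal-curve filter.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        return []
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite intensities")
    if np.ptp(img) == 0:
        return []  # featureless image: no foreground
    thr = _filters.threshold_otsu(img)
    fg = img > thr
    labels = _measure.label(fg, connectivity=2)
    masks: list[tuple[float, np.ndarray]] = []
    for lbl in range(1, labels.max() + 1):
        m = labels == lbl
        if m.sum() < min_area:
            continue
        cy = float(np.mean(np.nonzero(m)[0]))
        masks.append((cy, m))
    masks.sort(key=lambda t: t[0])
    return [InstanceMask(mask=m, score=1.0) for _, m in masks]


def segment_vertebrae(
    image: np.ndarray,
    backend: Callable[[np.ndarray], list[InstanceMask]] | None = None,
) -> list[InstanceMask]:
    """Run a detector backend on a grayscale radiograph.

    Degenerate images yield an empty list, never an exception; a failing
    backend is re-raised as :class:`BackendError` with context.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        return []
    if backend is None:
        backend = threshold_backend
    try:
        out = backend(img)
    except ValidationError:
        raise
    except Exception as exc:  # propagate with context, per the backend contract
        raise BackendError(f"detector backend {backend!r} failed: {exc}") from exc
    return list(out)


def mask_centroid(mask: InstanceMask | np.ndarray) -> CenterPoint:
    """Center of gravity of a mask: the unweighted arithmetic mean of its
    foreground pixel coordinates (pixel centers, not intensity-weighted)."""
    idx = -1
    if isinstance(mask, InstanceMask):
        m = mask.mask
    else:
        m = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if len(xs) == 0:
        raise ValidationError("cannot take the centroid of an empty mask")
    return CenterPoint(x=float(xs.mean()), y=float(ys.mean()), source_mask_index=idx)


# --------------------------------------------------------------------------
# Augmentation transforms
# --------------------------------------------------------------------------

AUGMENT_KINDS = ("edge_enhance", "noise", "resize", "contrast", "rotate")


def _edge_enhance(img: np.ndarray, rng, amount: float = 1.0, sigma: float = 1.0):
    blurred = _filters.gaussian(img, sigma=sigma, preserve_range=True)
    return img + amount * (img - blurred)

def _noise(img: np.ndarray, rng, sd: float = 1.0):
    return img + sd * rng.standard_normal(img.shape)

def _resize(img: np.ndarray, rng, scale: float | None = None,
            shape: tuple[int, int] | None = None):
    if shape is None:
        if scale is None:
            raise ValidationError("resize needs 'scale' or 'shape'")
        shape = (max(1, round(img.shape[0] * scale)),
                 max(1, round(img.shape[1] * scale)))
    return _transform.resize(img, shape, preserve_range=True, anti_aliasing=True)

def _contrast(img: np.ndarray, rng, gain: float = 1.0,
              midpoint: float | None = None,
              clip_range: tuple[float, float] = (0.0, 65535.0)):
    m = float(img.mean()) if midpoint is None else midpoint
    return np.clip(gain * (img - m) + m, *clip_range)

def _rotate(img: np.ndarray, rng, angle: float = 0.0, fill: float | None = None):
    if angle == 0.0:
        return img.copy()
    cval = float(np.median(img)) if fill is None else fill
    return _transform.rotate(img, angle, preserve_range=True, cval=cval)


_TRANSFORMS = {
    "edge_enhance": _edge_enhance,
    "noise": _noise,
    "resize": _resize,
    "contrast": _contrast,
    "rotate": _rotate,
}


def augment_image(
    image: np.ndarray,
    ops: Sequence[tuple[str, dict] | dict],
    seed: int | None = None,
) -> np.ndarray:
    """Apply an ordered list of augmentation transforms.

    Each op is ``("kind", {params})`` or ``{"kind": name, **params}`` with
    kind one of ``AUGMENT_KINDS``.  Deterministic for a fixed seed: all
    stochastic transforms draw from one seeded generator in op order.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=float)
    for op in ops:
        if isinstance(op, dict):
            params = dict(op)
            kind = params.pop("kind", None)
        else:
            kind, params = op[0], dict(op[1])
        if kind not in _TRANSFORMS:
            raise ValidationError(
                f"unknown transform kind {kind!r}; expected one of {AUGMENT_KINDS}"
            )
        out = np.asarray(_TRANSFORMS[kind](out, rng, **params), dtype=float)
    return out
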