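"""Stage-2: six-point landmark prediction on vertebral crops and the
crop <-> image coordinate mapping.

A vertebral body is annotated by six named points on a lateral view:
anterior-upper (AU), anterior-lower (AL), central-upper (CU),
central-lower (CL), posterior-upper (PU), posterior-lower (PL).
Landmarks are always handled by name, never by position, to prevent
silent anterior/posterior swaps.

Backends are pluggable callables ``(crop, window) -> LandmarkSet`` in the
crop frame.  The shipped reference backend is a truth oracle for phantom
images that looks up the ground-truth landmarks nearest to the crop window
and perturbs them with seeded zero-mean Gaussian noise of configurable SD —
the knob used to study how measurement statistics degrade with landmark
error.  A small trainable ridge-regression backend is provided as optional
scaffolding for experiments on real crops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ContractViolationError, ValidationError
from .segmentation import CenterPoint
from .spine_curve import CropWindow

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "predict_landmarks",
    "to_image_coords",
    "to_crop_coords",
    "OracleLandmarkBackend",
    "RidgeLandmarkBackend",
]

LANDMARK_NAMES = ("AU", "AL", "CU", "CL", "PU", "PL")

Point = tuple[float, float]


@dataclass(frozen=True)
class LandmarkSet:
    """The six named points of one vertebral body in a stated frame."""

    AU: Point
    AL: Point
    CU: Point
    CL: Point
    PU: Point
    PL: Point
    frame: str = "image"
    level: str | None = None

    def __post_init__(self) -> None:
        if self.frame not in ("crop", "image"):
            raise ValidationError(f"frame must be 'crop' or 'image', got {self.frame!r}")
        for name in LANDMARK_NAMES:
            p = getattr(self, name)
            if len(p) != 2 or not all(np.isfinite(p)):
                raise ValidationError(f"landmark {name} must be a finite (x, y) pair")
            object.__setattr__(self, name, (float(p[0]), float(p[1])))

    def as_array(self) -> np.ndarray:
        """(6, 2) array of (x, y) rows in canonical AU,AL,CU,CL,PU,PL order."""
        return np.array([getattr(self, n) for n in LANDMARK_NAMES], dtype=float)

    def as_dict(self) -> dict[str, Point]:
        return {n: getattr(self, n) for n in LANDMARK_NAMES}

    @classmethod
    def from_array(
        cls, arr: np.ndarray, frame: str = "image", level: str | None = None
    ) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6, 2):
            raise ValidationError(f"expected a (6, 2) array, got {arr.shape}")
        pts = {n: (float(x), float(y)) for n, (x, y) in zip(LANDMARK_NAMES, arr)}
        return cls(frame=frame, level=level, **pts)

    @classmethod
    def from_dict(
        cls, d: dict, frame: str = "image", level: str | None = None
    ) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in d]
        if missing:
            raise ValidationError(f"landmark set missing points: {missing}")
        pts = {n: (float(d[n][0]), float(d[n][1])) for n in LANDMARK_NAMES}
        return cls(frame=frame, level=level, **pts)

    def center(self) -> CenterPoint:
        c = self.as_array().mean(axis=0)
        return CenterPoint(x=float(c[0]), y=float(c[1]))

    def check_orientation(self, tol: float = 0.0) -> bool:
        """True when each upper point is cranial to its paired lower point
        (smaller y), up to ``tol`` pixels of slack for extreme deformity."""
        return all(
            getattr(self, up)[1] < getattr(self, lo)[1] + tol
            for up, lo in (("AU", "AL"), ("CU", "CL"), ("PU", "PL"))
        )


def to_image_coords(landmarks: LandmarkSet, window: CropWindow) -> LandmarkSet:
    """Map a crop-frame landmark set into image coordinates."""
    if landmarks.frame != "crop":
        raise ValidationError(f"expected crop-frame landmarks, got {landmarks.frame!r}")
    pts = window.crop_to_image(landmarks.as_array())
    return LandmarkSet.from_array(pts, frame="image", level=landmarks.level)


def to_crop_coords(landmarks: LandmarkSet, window: CropWindow) -> LandmarkSet:
    """Map an image-frame landmark set into a window's crop coordinates."""
    if landmarks.frame != "image":
        raise ValidationError(f"expected image-frame landmarks, got {landmarks.frame!r}")
    pts = window.image_to_crop(landmarks.as_array())
    return LandmarkSet.from_array(pts, frame="crop", level=landmarks.level)


def predict_landmarks(
    crop: np.ndarray,
    window: CropWindow,
    backend: Callable[[np.ndarray, CropWindow], LandmarkSet],
) -> LandmarkSet:
    """Run a landmark backend on one crop and validate its contract:
    six finite crop-frame coordinates inside the crop bounds."""
    crop = np.asarray(crop)
    if crop.shape != (window.side, window.side):
        raise ValidationError(
            f"crop shape {crop.shape} does not match window side {window.side}"
        )
    lms = backend(crop, window)
    if not isinstance(lms, LandmarkSet) or lms.frame != "crop":
        raise ContractViolationError(
            "backend must return a crop-frame LandmarkSet"
        )
    arr = lms.as_array()
    if not np.all(np.isfinite(arr)):
        raise ContractViolationError("backend returned non-finite coordinates")
    if arr.min() < 0 or arr.max() > window.side - 1:
        raise ContractViolationError(
            "backend returned coordinates outside the crop bounds"
        )
    return lms


class OracleLandmarkBackend:
    """Truth-lookup backend for phantom images.

    Holds ground-truth image-frame landmark sets; for each crop it selects
    the truth vertebra whose center is nearest the window center, maps it
    into the crop frame, and adds zero-mean Gaussian noise.  The noise is
    drawn as ``noise_sd * z`` with z standard normal from one seeded
    generator, so for a fixed seed and call order the perturbations scale
    linearly with ``noise_sd``.
    """

    def __init__(
        self,
        truth: Sequence[LandmarkSet],
        noise_sd: float = 0.0,
        seed: int | None = 0,
    ) -> None:
        if noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        self.truth = list(truth)
        if not self.truth:
            raise ValidationError("oracle backend needs at least one truth vertebra")
        for lm in self.truth:
            if lm.frame != "image":
                raise ValidationError("oracle truth must be in the image frame")
        self.noise_sd = float(noise_sd)
        self._rng = np.random.default_rng(seed)
        self._centers = np.array(
            [[lm.center().x, lm.center().y] for lm in self.truth], dtype=float
        )

    def __call__(self, crop: np.ndarray, window: CropWindow) -> LandmarkSet:
        wc = np.array([window.center.x, window.center.y])
        i = int(np.argmin(np.linalg.norm(self._centers - wc, axis=1)))
        truth = self.truth[i]
        pts = window.image_to_crop(truth.as_array())
        pts = pts + self.noise_sd * self._rng.standard_normal(pts.shape)
        pts = np.clip(pts, 0.0, window.side - 1)
        return LandmarkSet.from_array(pts, frame="crop", level=truth.level)


class RidgeLandmarkBackend:
    """Optional trainable backend: ridge regression from downsampled crop
    intensities to the 12 landmark coordinates.  Desk-scale scaffolding for
    experiments; not a substitute for a deep keypoint model."""

    def __init__(self, downsample: int = 8, alpha: float = 1.0) -> None:
        self.downsample = downsample
        self.alpha = alpha
        self._model = None
        self._side: int | None = None

    def _features(self, crop: np.ndarray) -> np.ndarray:
        d = self.downsample
        c = np.asarray(crop, dtype=float)
        h, w = (c.shape[0] // d) * d, (c.shape[1] // d) * d
        pooled = c[:h, :w].reshape(h // d, d, w // d, d).mean(axis=(1, 3))
        pooled = (pooled - pooled.mean()) / (pooled.std() + 1e-9)
        return pooled.ravel()

    def fit(
        self, crops: Sequence[np.ndarray], landmark_sets: Sequence[LandmarkSet]
    ) -> "RidgeLandmarkBackend":
        from sklearn.linear_model import Ridge

        X = np.stack([self._features(c) for c in crops])
        y = np.stack([lm.as_array().ravel() for lm in landmark_sets])
        self._side = int(np.asarray(crops[0]).shape[0])
        self._model = Ridge(alpha=self.alpha).fit(X, y)
        return self

    def __call__(self, crop: np.ndarray, window: CropWindow) -> LandmarkSet:
        if self._model is None:
            raise ValidationError("RidgeLandmarkBackend is not fitted")
        pts = self._model.predict(self._features(crop)[None, :])[0].reshape(6, 2)
        pts = np.clip(pts, 0.0, window.side - 1)
        return LandmarkSet.from_array(pts, frame="crop")
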