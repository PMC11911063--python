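"""RANSAC polynomial fit to detected vertebral centers, outlier rejection,
and fixed-size crop extraction.

The spine runs cranio-caudally, so the curve is parameterized as x = f(y)
with y the independent variable (a vertical spine is single-valued in y but
not in x).  Polynomial degree is capped at four.  Centers whose horizontal
deviation from the fitted curve exceeds the residual threshold are rejected
as false detections (ribs, diaphragm edges, airway walls).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FitError, ValidationError
from .segmentation import CenterPoint

__all__ = [
    "SpinalCurve",
    "CropWindow",
    "fit_spinal_curve",
    "enumerate_spinal_curve",
    "filter_centers",
    "crop_vertebra",
    "default_residual_threshold",
]

DEFAULT_CROP_SIDE = 224  # pixels; the side length of stage-2 input crops


@dataclass(frozen=True)
class SpinalCurve:
    """A fitted polynomial x = f(y) with per-center inlier flags."""

    degree: int
    coeffs: np.ndarray  # ascending order: coeffs[k] multiplies y**k
    inlier_flags: np.ndarray
    residual_threshold: float
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        object.__setattr__(
            self, "inlier_flags", np.asarray(self.inlier_flags, dtype=bool)
        )
        if not 1 <= self.degree <= 4:
            raise ValidationError(f"curve degree must be 1..4, got {self.degree}")

    def __call__(self, y):
        return np.polynomial.polynomial.polyval(np.asarray(y, dtype=float),
                                                self.coeffs)

    def residuals(self, centers: Sequence[CenterPoint]) -> np.ndarray:
        xs = np.array([c.x for c in centers], dtype=float)
        ys = np.array([c.y for c in centers], dtype=float)
        return np.abs(xs - self(ys))


@dataclass(frozen=True)
class CropWindow:
    """A side x side axis-aligned window; maps crop coordinates to image
    coordinates by an exact integer offset (crop (0,0) = image (x0, y0))."""

    center: CenterPoint
    side: int
    x0: int
    y0: int
    padding: tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValidationError("crop side must be positive")

    def crop_to_image(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 2) crop-frame (x, y) points to image coordinates."""
        return np.asarray(pts, dtype=float) + [self.x0, self.y0]

    def image_to_crop(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) - [self.x0, self.y0]


def default_residual_threshold(centers: Sequence[CenterPoint]) -> float:
    """Half the median nearest-neighbor spacing between centers.

    Scale-free across image resolutions; a center must deviate by more than
    half a typical inter-vertebral spacing to be called a false detection.
    """
    pts = np.array([[c.x, c.y] for c in centers], dtype=float)
    if len(pts) < 2:
        raise ValidationError("need at least 2 centers for a spacing estimate")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return 0.5 * float(np.median(d.min(axis=1)))


def _polyfit(ys: np.ndarray, xs: np.ndarray, degree: int) -> np.ndarray | None:
    """Least-squares x = f(y); None when the system is degenerate."""
    if len(np.unique(ys)) <= degree:
        return None
    # scale y for conditioning, then expand back to the raw-y basis
    ser = np.polynomial.Polynomial.fit(ys, xs, deg=degree)
    return ser.convert().coef


def _evaluate_candidate(
    ys: np.ndarray, xs: np.ndarray, sample: np.ndarray, degree: int, thr: float
):
    """Fit a minimal sample, refit on its consensus set, return the candidate.

    Returns (n_inliers, degree, ssr, flags, coeffs) or None when degenerate.
    Final flags are recomputed against the refit model so that every flagged
    inlier's residual is guaranteed <= thr.
    """
    coeffs = _polyfit(ys[sample], xs[sample], degree)
    if coeffs is None:
        return None
    resid = np.abs(xs - np.polynomial.polynomial.polyval(ys, coeffs))
    consensus = resid <= thr
    if consensus.sum() < degree + 1:
        return None
    refit = _polyfit(ys[consensus], xs[consensus], degree)
    if refit is None:
        return None
    resid = np.abs(xs - np.polynomial.polynomial.polyval(ys, refit))
    flags = resid <= thr
    if flags.sum() == 0:
        return None
    ssr = float(np.sum(resid[flags] ** 2))
    return int(flags.sum()), degree, ssr, flags, refit


def _better(a, b) -> bool:
    """Candidate ordering: more inliers, then lower degree, then lower SSR."""
    if b is None:
        return True
    return (a[0], -a[1], -a[2]) > (b[0], -b[1], -b[2])


def fit_spinal_curve(
    centers: Sequence[CenterPoint],
    max_degree: int = 4,
    residual_threshold: float | None = None,
    n_iter: int = 500,
    seed: int | None = 0,
) -> SpinalCurve:
    """RANSAC polynomial fit over degrees 1..min(max_degree, n-1).

    For each degree, minimal samples of size degree+1 are drawn; each sample
    model's consensus set is refit by least squares and candidates compete on
    (inlier count, lower degree, lower sum of squared inlier residuals).
    Deterministic for a fixed seed.  With the small point sets typical of a
    single radiograph, ``n_iter`` = 500 is exhaustive in practice.
    """
    n = len(centers)
    if n < 2:
        raise ValidationError(f"need at least 2 centers to fit a curve, got {n}")
    xs = np.array([c.x for c in centers], dtype=float)
    ys = np.array([c.y for c in centers], dtype=float)
    if residual_threshold is None:
        residual_threshold = default_residual_threshold(centers)
    if residual_threshold <= 0:
        raise ValidationError("residual_threshold must be positive")

    rng = np.random.default_rng(seed)
    degrees = range(1, min(max_degree, n - 1) + 1)
    best = None
    any_sample = False
    for degree in degrees:
        m = degree + 1
        seen: set[bytes] = set()
        for _ in range(n_iter):
            sample = np.sort(rng.choice(n, size=m, replace=False))
            key = sample.tobytes()
            if key in seen:
                continue
            seen.add(key)
            cand = _evaluate_candidate(ys, xs, sample, degree, residual_threshold)
            if cand is None:
                continue
            any_sample = True
            if _better(cand, best):
                best = cand
    if best is None:
        if not any_sample:
            raise FitError(
                "all RANSAC samples were degenerate (duplicate y values make "
                "x = f(y) underdetermined); check for stacked detections"
            )
        raise FitError("no RANSAC candidate produced a consensus set")
    _, degree, _, flags, coeffs = best
    return SpinalCurve(
        degree=degree,
        coeffs=coeffs,
        inlier_flags=flags,
        residual_threshold=float(residual_threshold),
        seed=seed,
    )


def enumerate_spinal_curve(
    centers: Sequence[CenterPoint],
    max_degree: int = 4,
    residual_threshold: float | None = None,
) -> SpinalCurve:
    """Exhaustive counterpart of :func:`fit_spinal_curve`: evaluates every
    minimal sample of every degree.  Feasible for small center counts; used
    as the deterministic optimum that randomized RANSAC should reach."""
    n = len(centers)
    if n < 2:
        raise ValidationError(f"need at least 2 centers to fit a curve, got {n}")
    xs = np.array([c.x for c in centers], dtype=float)
    ys = np.array([c.y for c in centers], dtype=float)
    if residual_threshold is None:
        residual_threshold = default_residual_threshold(centers)
    best = None
    any_sample = False
    for degree in range(1, min(max_degree, n - 1) + 1):
        for comb in itertools.combinations(range(n), degree + 1):
            cand = _evaluate_candidate(
                ys, xs, np.array(comb), degree, residual_threshold
            )
            if cand is None:
                continue
            any_sample = True
            if _better(cand, best):
                best = cand
    if best is None:
        if not any_sample:
            raise FitError("all minimal samples were degenerate")
        raise FitError("no candidate produced a consensus set")
    _, degree, _, flags, coeffs = best
    return SpinalCurve(
        degree=degree,
        coeffs=coeffs,
        inlier_flags=flags,
        residual_threshold=float(residual_threshold),
        seed=None,
    )


def filter_centers(
    centers: Sequence[CenterPoint], curve: SpinalCurve
) -> list[CenterPoint]:
    """Keep exactly the inlier-flagged centers, order preserved."""
    if len(centers) != len(curve.inlier_flags):
        raise ValidationError(
            f"{len(centers)} centers but {len(curve.inlier_flags)} inlier flags; "
            "the curve must have been fitted on these centers"
        )
    return [c for c, keep in zip(centers, curve.inlier_flags) if keep]


def crop_vertebra(
    image: np.ndarray,
    center: CenterPoint,
    side: int = DEFAULT_CROP_SIDE,
    fill: float | None = None,
) -> tuple[np.ndarray, CropWindow]:
    """Extract a side x side crop centered on a vertebral center.

    The window origin is ``round(center) - side // 2`` in each axis, so for
    even ``side`` the rounded center lands on crop pixel (side//2, side//2).
    Regions outside the image are padded with ``fill`` (default: the image
    median, a background-intensity proxy) and recorded per edge.  The window
    transform is an exact integer translation, so crop->image->crop round
    trips are lossless.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("image must be 2-D")
    h, w = img.shape
    if not (0 <= center.x <= w - 1 and 0 <= center.y <= h - 1):
        raise ValidationError(
            f"center ({center.x}, {center.y}) lies outside the {w}x{h} image"
        )
    if side <= 0:
        raise ValidationError("crop side must be positive")
    x0 = int(round(center.x)) - side // 2
    y0 = int(round(center.y)) - side // 2
    xa, xb = max(x0, 0), min(x0 + side, w)
    ya, yb = max(y0, 0), min(y0 + side, h)
    pad_top = ya - y0
    pad_bottom = (y0 + side) - yb
    pad_left = xa - x0
    pad_right = (x0 + side) - xb
    cval = float(np.median(img)) if fill is None else float(fill)
    crop = np.full((side, side), cval, dtype=float)
    crop[pad_top:side - pad_bottom, pad_left:side - pad_right] = img[ya:yb, xa:xb]
    window = CropWindow(
        center=center,
        side=side,
        x0=x0,
        y0=y0,
        padding=(pad_top, pad_bottom, pad_left, pad_right),
    )
    return crop, window
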