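"""Synthetic lateral spine-radiograph phantoms with exact ground truth.

A phantom emulates the geometry that the detection and morphometry stages
care about: a vertically running column of brighter-than-background
vertebral bodies whose centers lie on a low-degree polynomial curve
x = f(y), with per-level deformities (wedge, biconcave, crush) at a
controlled severity, optional confuser structures that mimic the common
false-detection sources on real radiographs (diaphragm edge, posterior
airway wall, rib overlap), additive Gaussian noise and contrast variation.
It is not a photorealistic radiograph: no exposure physics, no soft-tissue
texture, no pedicle/process anatomy.

Each vertebra is rendered as a filled hexagon through its six landmarks
(AU, CU, PU on the upper endplate; AL, CL, PL on the lower), so the truth
landmarks are exactly consistent with the rendered shape.  Deformity
severity s maps onto landmark geometry so that the defining height ratio
reduction equals s:

* wedge:     anterior height A = (1 - s) * P, so A/P = 1 - s
             (the upper endplate tilts; C = (A + P) / 2 follows),
* biconcave: central height C = (1 - s) * P, so C/P = 1 - s
             (both endplates dip centrally, symmetric about the center),
* crush:     all three heights scale by (1 - s); within-vertebra ratios
             stay 1, as they do in real crush fractures.

For wedge and biconcave phantoms the QM collapse percent recovered from
the truth landmarks therefore equals 100 * s by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon
from skimage.filters import gaussian as _gaussian

from .errors import SizingError, ValidationError
from .landmark import LandmarkSet
from .morphometry import VertebraMorphometry, measure
from .segmentation import CenterPoint

__all__ = [
    "LEVELS_T4_L5",
    "Deformity",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "write_truth",
]

#: Vertebral levels covered by the measurement range, cranial to caudal.
LEVELS_T4_L5 = tuple(f"T{i}" for i in range(4, 13)) + tuple(f"L{i}" for i in range(1, 6))

DEFORMITY_TYPES = ("none", "wedge", "biconcave", "crush")

CONFUSER_KINDS = ("diaphragm", "airway", "rib")

#: Gray-level convention: 16-bit range [0, 65535].
GRAY_MAX = 65535.0


@dataclass(frozen=True)
class Deformity:
    type: str = "none"
    severity: float = 0.0

    def __post_init__(self) -> None:
        if self.type not in DEFORMITY_TYPES:
            raise ValidationError(
                f"deformity type must be one of {DEFORMITY_TYPES}, got {self.type!r}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ValidationError(
                f"severity must be in [0, 1], got {self.severity}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic spine radiograph.

    ``curve_coeffs`` are ascending polynomial coefficients of the spinal
    midline x = f(y), degree <= 4.  ``size_gradient`` grows vertebral width
    and height multiplicatively per level moving caudally (lumbar vertebrae
    are larger than thoracic).  ``deformities`` maps level labels to
    :class:`Deformity`.
    """

    image_size: tuple[int, int] = (880, 420)  # (height, width) px
    n_vertebrae: int = 14  # T4..L5
    curve_coeffs: tuple[float, ...] = (210.0, 0.05, -6.0e-5)
    base_width: float = 64.0  # most cranial vertebra, px
    base_height: float = 34.0
    size_gradient: float = 1.03  # per-level multiplicative growth
    gap: float = 10.0  # intervertebral spacing, px
    deformities: Mapping[str, Deformity] = field(default_factory=dict)
    bone_intensity: float = 40000.0
    background_intensity: float = 12000.0
    noise_sd: float = 200.0
    confusers: tuple[str, ...] = ()
    anterior_side: str = "left"
    edge_sigma: float = 0.8  # Gaussian smoothing of rendered edges, px
    top_margin: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValidationError("n_vertebrae must be >= 1")
        if len(self.curve_coeffs) > 5:
            raise ValidationError("spinal curve degree must be <= 4")
        if self.anterior_side not in ("left", "right"):
            raise ValidationError("anterior_side must be 'left' or 'right'")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        for kind in self.confusers:
            if kind not in CONFUSER_KINDS:
                raise ValidationError(
                    f"unknown confuser {kind!r}; expected one of {CONFUSER_KINDS}"
                )
        for level, d in self.deformities.items():
            if not isinstance(d, Deformity):
                raise ValidationError(
                    f"deformities[{level!r}] must be a Deformity instance"
                )

    def levels(self) -> tuple[str, ...]:
        """Level labels, starting at T4; beyond L5 synthetic labels V15.. are
        used (no clinical meaning, keeps records addressable)."""
        extra = tuple(f"V{i}" for i in range(15, self.n_vertebrae + 1))
        return (LEVELS_T4_L5 + extra)[: self.n_vertebrae]


@dataclass(frozen=True)
class PhantomCase:
    """A generated phantom: the raster plus exact per-vertebra ground truth."""

    image: np.ndarray
    truth_masks: list[np.ndarray]
    truth_landmarks: list[LandmarkSet]
    truth_morphometry: list[VertebraMorphometry]
    truth_centers: list[CenterPoint]
    spec: PhantomSpec


def _midline(spec: PhantomSpec, y: float) -> float:
    return float(np.polynomial.polynomial.polyval(y, np.asarray(spec.curve_coeffs)))


def _vertebra_landmarks(
    spec: PhantomSpec, level: str, xc: float, yc: float, w: float, h: float
) -> LandmarkSet:
    """Six landmarks of one vertebra with its deformity applied.

    The undeformed template is an axis-aligned w x h rectangle centered at
    (xc, yc); deformity moves points per the severity mapping in the module
    docstring.  Anterior is the ``anterior_side`` of the image.
    """
    d = spec.deformities.get(level, Deformity())
    s = d.severity if d.type != "none" else 0.0
    sign = -1.0 if spec.anterior_side == "left" else 1.0
    xa, xp = xc + sign * w / 2.0, xc - sign * w / 2.0
    yt, yb = yc - h / 2.0, yc + h / 2.0

    if d.type == "crush":
        half = (1.0 - s) * h / 2.0
        yt, yb = yc - half, yc + half

    au_y = pu_y = yt
    cu_y, cl_y = yt, yb
    al_y = pl_y = yb
    if d.type == "wedge":
        au_y = yb - (1.0 - s) * h  # A = (1-s) h
        cu_y = (au_y + pu_y) / 2.0  # CU on the straight tilted endplate
    elif d.type == "biconcave":
        c_half = (1.0 - s) * h / 2.0
        cu_y, cl_y = yc - c_half, yc + c_half
    elif d.type == "crush":
        cu_y, cl_y = yt, yb  # already rescaled above

    return LandmarkSet(
        AU=(xa, au_y), AL=(xa, al_y),
        CU=(xc, cu_y), CL=(xc, cl_y),
        PU=(xp, pu_y), PL=(xp, pl_y),
        frame="image", level=level,
    )


def _render_vertebra(canvas: np.ndarray, lm: LandmarkSet, value: float) -> np.ndarray:
    """Fill the hexagon AU-CU-PU-PL-CL-AL; returns the binary mask."""
    pts = np.array([lm.AU, lm.CU, lm.PU, lm.PL, lm.CL, lm.AL], dtype=float)
    rr, cc = _draw_polygon(pts[:, 1], pts[:, 0], shape=canvas.shape)
    canvas[rr, cc] = value
    mask = np.zeros(canvas.shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_stroke(canvas: np.ndarray, xs, ys, radius: float, value: float) -> None:
    for x, y in zip(xs, ys):
        rr, cc = _draw_disk((y, x), radius, shape=canvas.shape)
        canvas[rr, cc] = value


def _draw_confusers(canvas: np.ndarray, spec: PhantomSpec) -> None:
    """Bright curvilinear edges mimicking non-vertebral structures.

    The diaphragm and airway strokes are placed well lateral of the spinal
    midline so the reference detector sees them as separate components that
    only the curve filter can reject; the rib stroke deliberately crosses a
    vertebral margin (a merged-component stress case).
    """
    h, w = canvas.shape
    sign = -1.0 if spec.anterior_side == "left" else 1.0
    mid_top = _midline(spec, 0.25 * h)
    if "diaphragm" in spec.confusers:
        # dome-shaped edge in the anterior lower half of the field
        t = np.linspace(0.0, 1.0, 300)
        xs = mid_top + sign * (0.40 * w + 0.0 * t) - sign * 0.25 * w * t
        xs = np.clip(xs, 8, w - 9)
        ys = np.clip(0.62 * h + 0.18 * h * (t - 0.5) ** 2 * 4.0, 8, h - 9)
        _draw_stroke(canvas, xs, ys, 5.0, spec.bone_intensity)
    if "airway" in spec.confusers:
        # near-vertical posterior airway wall
        t = np.linspace(0.0, 1.0, 300)
        ys = np.clip((0.10 + 0.45 * t) * h, 8, h - 9)
        xs = np.clip(
            mid_top - sign * (0.35 * w) + 6.0 * np.sin(3.0 * np.pi * t), 8, w - 9
        )
        _draw_stroke(canvas, xs, ys, 4.0, spec.bone_intensity)
    if "rib" in spec.confusers:
        # short oblique edge crossing the column near the top
        t = np.linspace(0.0, 1.0, 120)
        xs = np.clip(mid_top + sign * w * (0.30 - 0.45 * t), 8, w - 9)
        ys = np.clip(0.12 * h + 0.08 * h * t, 8, h - 9)
        _draw_stroke(canvas, xs, ys, 3.0, spec.bone_intensity)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; deterministic for a fixed spec + seed."""
    H, W = spec.image_size
    canvas = np.full((H, W), float(spec.background_intensity))

    y_cursor = float(spec.top_margin)
    landmarks: list[LandmarkSet] = []
    centers: list[CenterPoint] = []
    sizes: list[tuple[float, float]] = []
    for i, level in enumerate(spec.levels()):
        g = spec.size_gradient ** i
        w_i, h_i = spec.base_width * g, spec.base_height * g
        yc = y_cursor + h_i / 2.0
        xc = _midline(spec, yc)
        lm = _vertebra_landmarks(spec, level, xc, yc, w_i, h_i)
        arr = lm.as_array()
        if (arr[:, 0].min() < 0 or arr[:, 0].max() > W - 1
                or arr[:, 1].min() < 0 or arr[:, 1].max() > H - 1):
            raise SizingError(
                f"vertebra {level} landmarks fall outside the {W}x{H} image; "
                "enlarge image_size or shrink the column"
            )
        landmarks.append(lm)
        centers.append(CenterPoint(x=xc, y=yc, source_mask_index=i))
        sizes.append((w_i, h_i))
        y_cursor += h_i + spec.gap

    masks = [_render_vertebra(canvas, lm, spec.bone_intensity) for lm in landmarks]
    _draw_confusers(canvas, spec)

    if spec.edge_sigma > 0:
        canvas = _gaussian(canvas, sigma=spec.edge_sigma, preserve_range=True)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + spec.noise_sd * rng.standard_normal(canvas.shape)
    canvas = np.clip(canvas, 0.0, GRAY_MAX)

    morph = [measure(lm) for lm in landmarks]
    return PhantomCase(
        image=canvas,
        truth_masks=masks,
        truth_landmarks=landmarks,
        truth_morphometry=morph,
        truth_centers=centers,
        spec=spec,
    )


def write_truth(
    case: PhantomCase,
    path: str | Path,
    case_id: str = "phantom",
    image_id: str = "phantom-000",
) -> Path:
    """Write the ground-truth landmarks as an annotation file (JSON or CSV
    by extension) in the shared schema; round-trips through
    :func:`vertemorph.io.read_annotations`."""
    from .io import AnnotationRecord, write_annotations

    records = [
        AnnotationRecord(
            case_id=case_id,
            image_id=image_id,
            level=lm.level or f"V{i + 1}",
            evaluator="truth",
            landmarks=lm,
        )
        for i, lm in enumerate(case.truth_landmarks)
    ]
    return write_annotations(records, path)
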