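"""Quantitative morphometry: heights, height ratios, collapse percent,
QM status bins, and algorithm-vs-reference discrepancy flags.

From the six landmarks, three vertebral body heights are measured as
Euclidean distances between paired upper/lower points — anterior
A = |AU - AL|, central C = |CU - CL|, posterior P = |PU - PL| — and
summarized by the height ratios C/A, C/P and A/P.  Collapse percent is
100 * (1 - min(A/P, C/P)): wedge deformity lowers A/P, biconcave lowers
C/P, and either is measurable within a single vertebra against its own
posterior height.  Crush deformity (posterior loss) is invisible to
within-vertebra ratios; an optional helper compares P against adjacent
vertebrae instead.

QM status bins are half-open: [0,20) "<20", [20,25) "20-25",
[25,40) "25-40", [40,inf) ">40" — a collapse of exactly 25% falls in
"25-40", exactly 40% in ">40".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .landmark import LandmarkSet

__all__ = [
    "QM_BINS",
    "VertebraMorphometry",
    "compute_heights",
    "compute_ratios",
    "collapse_percent",
    "posterior_collapse_percent",
    "qm_status",
    "flag_discrepancy",
    "measure",
]

QM_BINS = ("<20", "20-25", "25-40", ">40")
_BIN_EDGES = (20.0, 25.0, 40.0)

RATIO_NAMES = ("C/A", "C/P", "A/P")

DISCREPANCY_THRESHOLD = 0.2  # |algorithm ratio - reference ratio| flagging cutoff


@dataclass(frozen=True)
class VertebraMorphometry:
    A: float
    C: float
    P: float
    ratio_CA: float
    ratio_CP: float
    ratio_AP: float
    collapse_pct: float
    qm_status: str
    level: str | None = None

    @property
    def ratios(self) -> tuple[float, float, float]:
        return (self.ratio_CA, self.ratio_CP, self.ratio_AP)


def compute_heights(landmarks: LandmarkSet) -> tuple[float, float, float]:
    """Anterior, central and posterior heights as Euclidean distances
    between the paired upper/lower landmarks."""
    heights = []
    for up, lo, name in (("AU", "AL", "A"), ("CU", "CL", "C"), ("PU", "PL", "P")):
        p, q = getattr(landmarks, up), getattr(landmarks, lo)
        h = float(np.hypot(p[0] - q[0], p[1] - q[1]))
        if h <= 0.0:
            raise ValidationError(
                f"height {name} is zero: landmarks {up} and {lo} coincide"
            )
        heights.append(h)
    return tuple(heights)


def compute_ratios(A: float, C: float, P: float) -> tuple[float, float, float]:
    """Height ratios (C/A, C/P, A/P)."""
    if min(A, C, P) <= 0:
        raise ValidationError(f"heights must be positive, got A={A}, C={C}, P={P}")
    return (C / A, C / P, A / P)


def collapse_percent(ratios: Sequence[float]) -> float:
    """Collapse percent from (C/A, C/P, A/P): 100 * (1 - min(A/P, C/P)),
    floored at zero (taller-than-posterior vertebrae count as 0% collapse)."""
    _, cp, ap = _validate_ratios(ratios)
    return max(0.0, 100.0 * (1.0 - min(ap, cp)))


def posterior_collapse_percent(P: float, adjacent_P: Sequence[float]) -> float:
    """Optional crush-deformity measure: loss of posterior height relative to
    the mean posterior height of adjacent vertebrae.  Off the default path —
    within-vertebra ratios cannot see posterior loss."""
    if P <= 0 or len(adjacent_P) == 0 or min(adjacent_P) <= 0:
        raise ValidationError("posterior heights must be positive and nonempty")
    return max(0.0, 100.0 * (1.0 - P / float(np.mean(adjacent_P))))


def qm_status(collapse_pct: float) -> str:
    """Assign the QM status bin under the half-open convention documented in
    the module docstring."""
    if not np.isfinite(collapse_pct) or collapse_pct < 0:
        raise ValidationError(f"collapse percent must be >= 0, got {collapse_pct}")
    for edge, label in zip(_BIN_EDGES, QM_BINS[:-1]):
        if collapse_pct < edge:
            return label
    return QM_BINS[-1]


def flag_discrepancy(
    pred_ratios: Sequence[float],
    ref_ratios: Sequence[float],
    threshold: float = DISCREPANCY_THRESHOLD,
) -> tuple[bool, list[str]]:
    """Flag a vertebra when any |predicted - reference| ratio difference
    reaches the threshold (inclusive).  Returns the flag and the names of
    the offending ratios."""
    pred = _validate_ratios(pred_ratios)
    ref = _validate_ratios(ref_ratios)
    # inclusive cutoff, tolerant to float representation of the difference
    eps = 1e-9 * max(1.0, threshold)
    offending = [
        name
        for name, p, r in zip(RATIO_NAMES, pred, ref)
        if abs(p - r) >= threshold - eps
    ]
    return (len(offending) > 0, offending)


def measure(landmarks: LandmarkSet) -> VertebraMorphometry:
    """Full morphometry of one landmark set: heights, ratios, collapse
    percent and QM status."""
    A, C, P = compute_heights(landmarks)
    ca, cp, ap = compute_ratios(A, C, P)
    pct = collapse_percent((ca, cp, ap))
    return VertebraMorphometry(
        A=A, C=C, P=P,
        ratio_CA=ca, ratio_CP=cp, ratio_AP=ap,
        collapse_pct=pct, qm_status=qm_status(pct),
        level=landmarks.level,
    )


def _validate_ratios(ratios: Sequence[float]) -> tuple[float, float, float]:
    r = tuple(float(v) for v in ratios)
    if len(r) != 3:
        raise ValidationError(f"expected three ratios (C/A, C/P, A/P), got {len(r)}")
    if any(not np.isfinite(v) or v <= 0 for v in r):
        raise ValidationError(f"ratios must be positive and finite, got {r}")
    return r
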