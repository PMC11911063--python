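"""Observer-agreement evaluation: detection metrics, size-normalized
landmark errors, normality-gated correlation, and Bland–Altman agreement
with QM-subgroup and proportional-bias analysis.

Conventions
-----------
* Detections are matched to reference vertebrae one-to-one, greedily in
  increasing center-distance order; a prediction is a true positive iff it
  matches within the tolerance radius tau (by default half the local
  reference vertebral height).
* Landmark errors are reported separately per axis as percentages of the
  reference vertebral body's width (x) and height (y).
* Paired differences are oriented algorithm - reference.
* Correlation uses Pearson when both series pass the Shapiro–Wilk
  normality test at alpha = 0.05, Spearman otherwise.
* Limits of agreement are MD +/- 1.96 * SD of the differences; subgroup
  within-LOA percentages are computed against the single global LOA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .errors import ValidationError
from .landmark import LANDMARK_NAMES, LandmarkSet
from .morphometry import (
    RATIO_NAMES,
    flag_discrepancy,
    measure,
)
from .segmentation import CenterPoint

__all__ = [
    "DetectionCounts",
    "DetectionMetrics",
    "LandmarkErrorRecord",
    "CorrelationResult",
    "BlandAltmanResult",
    "match_detections",
    "detection_metrics",
    "vertebra_dimensions",
    "landmark_errors",
    "correlation",
    "bland_altman",
    "evaluate_pipeline",
]

LOA_FACTOR = 1.96  # MD +/- 1.96 SD brackets ~95% of normal differences


@dataclass(frozen=True)
class DetectionCounts:
    n_reference: int
    TP: int
    FP: int
    n_images: int = 1

    def __post_init__(self) -> None:
        if min(self.n_reference, self.TP, self.FP) < 0 or self.n_images < 1:
            raise ValidationError("counts must be nonnegative and n_images >= 1")
        if self.TP > self.n_reference:
            raise ValidationError("TP cannot exceed the reference count")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(
            self.n_reference + other.n_reference,
            self.TP + other.TP,
            self.FP + other.FP,
            self.n_images + other.n_images,
        )


@dataclass(frozen=True)
class DetectionMetrics:
    """Sensitivity and precision as fractions (None when undefined because
    of a zero denominator), plus false positives per image."""

    sensitivity: float | None
    precision: float | None
    fp_per_image: float

    @property
    def sensitivity_pct(self) -> float | None:
        return None if self.sensitivity is None else round(100 * self.sensitivity, 1)

    @property
    def precision_pct(self) -> float | None:
        return None if self.precision is None else round(100 * self.precision, 1)


def match_detections(
    pred_centers: Sequence[CenterPoint],
    ref_centers: Sequence[CenterPoint],
    tau: float | Sequence[float],
    n_images: int = 1,
) -> tuple[list[bool], DetectionCounts]:
    """Greedy one-to-one matching of predictions to reference centers.

    All (prediction, reference) pairs are visited in increasing distance
    order; a pair is matched when both ends are still free and the distance
    is within tau (scalar, or one radius per reference).  Returns per-
    prediction TP flags and the aggregated counts.  A nonempty prediction
    list against an empty reference yields all false positives.
    """
    taus = np.asarray(tau, dtype=float)
    if taus.ndim == 0:
        taus = np.full(len(ref_centers), float(taus))
    if len(taus) != len(ref_centers):
        raise ValidationError("need one tau per reference center (or a scalar)")
    if len(ref_centers) and taus.min() <= 0:
        raise ValidationError("tau must be positive")

    pairs = []
    for i, p in enumerate(pred_centers):
        for j, r in enumerate(ref_centers):
            d = math.hypot(p.x - r.x, p.y - r.y)
            if d <= taus[j]:
                pairs.append((d, i, j))
    pairs.sort()
    pred_used = [False] * len(pred_centers)
    ref_used = [False] * len(ref_centers)
    for _, i, j in pairs:
        if not pred_used[i] and not ref_used[j]:
            pred_used[i] = True
            ref_used[j] = True
    tp = sum(pred_used)
    counts = DetectionCounts(
        n_reference=len(ref_centers),
        TP=tp,
        FP=len(pred_centers) - tp,
        n_images=n_images,
    )
    return pred_used, counts


def detection_metrics(counts: DetectionCounts) -> DetectionMetrics:
    """Sensitivity = TP / reference count; precision = TP / (TP + FP);
    FP rate = FP / images.  Zero denominators yield None markers."""
    sens = counts.TP / counts.n_reference if counts.n_reference else None
    denom = counts.TP + counts.FP
    prec = counts.TP / denom if denom else None
    return DetectionMetrics(
        sensitivity=sens,
        precision=prec,
        fp_per_image=counts.FP / counts.n_images,
    )


def vertebra_dimensions(ref: LandmarkSet) -> tuple[float, float]:
    """Reference vertebral body size used to normalize landmark errors:
    width = mean of the upper and lower edge spans |PU-AU|, |PL-AL|;
    height = mean of the anterior and posterior heights |AU-AL|, |PU-PL|."""
    a = ref.as_dict()
    def dist(p, q):
        return math.hypot(p[0] - q[0], p[1] - q[1])
    width = 0.5 * (dist(a["PU"], a["AU"]) + dist(a["PL"], a["AL"]))
    height = 0.5 * (dist(a["AU"], a["AL"]) + dist(a["PU"], a["PL"]))
    if width <= 0 or height <= 0:
        raise ValidationError("degenerate vertebra: zero width or height")
    return width, height


@dataclass(frozen=True)
class LandmarkErrorRecord:
    """Per-landmark |dx|, |dy| as percent of reference width/height."""

    x_error_pct: dict[str, float]
    y_error_pct: dict[str, float]
    vertebra_id: str = ""
    qm_bin: str | None = None
    region: str | None = None

    def mean_error_pct(self) -> float:
        vals = list(self.x_error_pct.values()) + list(self.y_error_pct.values())
        return float(np.mean(vals))


def landmark_errors(
    pred: LandmarkSet,
    ref: LandmarkSet,
    vertebra_id: str = "",
    qm_bin: str | None = None,
    region: str | None = None,
) -> LandmarkErrorRecord:
    """Size-normalized landmark errors of one vertebra, per axis."""
    if pred.frame != ref.frame:
        raise ValidationError(
            f"frame mismatch: pred in {pred.frame!r}, ref in {ref.frame!r}"
        )
    width, height = vertebra_dimensions(ref)
    xe, ye = {}, {}
    for n in LANDMARK_NAMES:
        px, py = getattr(pred, n)
        rx, ry = getattr(ref, n)
        xe[n] = 100.0 * abs(px - rx) / width
        ye[n] = 100.0 * abs(py - ry) / height
    return LandmarkErrorRecord(
        x_error_pct=xe, y_error_pct=ye,
        vertebra_id=vertebra_id, qm_bin=qm_bin, region=region,
    )


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    method: str | None  # "pearson" | "spearman" | None (undefined marker)
    coefficient: float
    p_value: float
    normality_p: tuple[float, float]
    n: int


def _spearman_exact_p(a: np.ndarray, b: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    ra = _stats.rankdata(a)
    rb = _stats.rankdata(b)
    count = 0
    total = 0
    for perm in itertools.permutations(rb):
        rho = np.corrcoef(ra, perm)[0, 1]
        if abs(rho) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlation(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Normality-gated correlation of two paired series.

    Shapiro–Wilk is run on each series; Pearson is used iff both p-values
    are >= alpha, Spearman otherwise.  Spearman p-values use the
    large-sample t approximation, switching to an exact rank-permutation
    test below n = 10.  Constant series yield an undefined-correlation
    marker (method None, NaN coefficient).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("series must be 1-D and equal length")
    n = len(a)
    if n < 4:
        raise ValidationError(f"need at least 4 pairs, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(None, float("nan"), float("nan"),
                                 (float("nan"), float("nan")), n)
    pa = float(_stats.shapiro(a).pvalue)
    pb = float(_stats.shapiro(b).pvalue)
    if pa >= alpha and pb >= alpha:
        r, p = _stats.pearsonr(a, b)
        return CorrelationResult("pearson", float(r), float(p), (pa, pb), n)
    rho, p = _stats.spearmanr(a, b)
    if n < 10:
        p = _spearman_exact_p(a, b, float(rho))
    return CorrelationResult("spearman", float(rho), float(p), (pa, pb), n)


@dataclass(frozen=True)
class BlandAltmanResult:
    md: float
    sd_diff: float
    loa: tuple[float, float]
    within_loa: np.ndarray
    trend_slope: float | None
    trend_p: float | None
    trend_r2: float | None
    subgroups: list[dict] = field(default_factory=list)

    @property
    def within_loa_fraction(self) -> float:
        return float(np.mean(self.within_loa))


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    qm_bins: Sequence[str] | None = None,
) -> BlandAltmanResult:
    """Bland–Altman agreement of paired series, differences a - b.

    LOA = MD +/- 1.96 * sample SD (ddof = 1).  Within-LOA flags are
    computed for every pair against the global LOA (inclusive), then
    aggregated per QM bin when bins are given.  Proportional bias is the
    simple linear regression of the difference on the pair mean (slope,
    p, R^2); with zero-variance differences the LOA collapses to [MD, MD]
    and the trend is undefined (None markers).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("series must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ValidationError(f"need at least 2 pairs, got {n}")
    d = a - b
    mean_pair = (a + b) / 2.0
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (md - LOA_FACTOR * sd, md + LOA_FACTOR * sd)
    within = (d >= loa[0]) & (d <= loa[1])

    if sd == 0 or np.ptp(mean_pair) == 0:
        slope = p = r2 = None
    else:
        fit = _stats.linregress(mean_pair, d)
        slope, p, r2 = float(fit.slope), float(fit.pvalue), float(fit.rvalue**2)

    subgroups: list[dict] = []
    if qm_bins is not None:
        qm_bins = list(qm_bins)
        if len(qm_bins) != n:
            raise ValidationError("need one QM bin per pair")
        for label in dict.fromkeys(qm_bins):  # first-appearance order
            idx = [i for i, q in enumerate(qm_bins) if q == label]
            dd = d[idx]
            subgroups.append(
                {
                    "qm_bin": label,
                    "n": len(idx),
                    "md": float(dd.mean()),
                    "sd": float(dd.std(ddof=1)) if len(idx) > 1 else 0.0,
                    "within_loa_pct": float(100.0 * within[idx].mean()),
                }
            )
    return BlandAltmanResult(
        md=md, sd_diff=sd, loa=loa, within_loa=within,
        trend_slope=slope, trend_p=p, trend_r2=r2, subgroups=subgroups,
    )


# --------------------------------------------------------------------------
# Full report
# --------------------------------------------------------------------------

def _summarize_errors(records: Sequence[LandmarkErrorRecord]) -> dict:
    if not records:
        return {"n": 0}
    xs = {n: [r.x_error_pct[n] for r in records] for n in LANDMARK_NAMES}
    ys = {n: [r.y_error_pct[n] for r in records] for n in LANDMARK_NAMES}
    return {
        "n": len(records),
        "mean_x_error_pct": {n: float(np.mean(v)) for n, v in xs.items()},
        "mean_y_error_pct": {n: float(np.mean(v)) for n, v in ys.items()},
        "overall_mean_error_pct": float(
            np.mean([r.mean_error_pct() for r in records])
        ),
    }


def evaluate_pipeline(
    pred_records: Sequence,
    ref_records: Sequence,
    tau_factor: float = 0.5,
    discrepancy_threshold: float = 0.2,
    alpha: float = 0.05,
) -> dict:
    """Full evaluation of predicted vs reference annotations.

    Records are paired by (image_id, level).  The report contains detection
    counts and metrics (per-reference tau = tau_factor x local vertebral
    height), landmark-error summaries stratified by region and reference QM
    bin, one correlation and one Bland–Altman analysis per height ratio
    (C/A, C/P, A/P), and the list of vertebrae whose ratios disagree by at
    least the discrepancy threshold.  Reference vertebrae without a
    prediction count as non-detections and are excluded from paired
    statistics.
    """
    ref_by_key = {(r.image_id, r.level): r for r in ref_records}
    pred_by_key = {(r.image_id, r.level): r for r in pred_records}
    if not set(ref_by_key) & set(pred_by_key):
        raise ValidationError("no overlapping (image_id, level) keys to evaluate")

    # detection, per image
    images = sorted({k[0] for k in ref_by_key} | {k[0] for k in pred_by_key})
    total = DetectionCounts(0, 0, 0, 1)
    first = True
    for image_id in images:
        refs = [r for r in ref_records if r.image_id == image_id]
        preds = [r for r in pred_records if r.image_id == image_id]
        taus = [tau_factor * vertebra_dimensions(r.landmarks)[1] for r in refs]
        _, counts = match_detections(
            [r.landmarks.center() for r in preds],
            [r.landmarks.center() for r in refs],
            taus if refs else 1.0,
            n_images=1,
        )
        total = counts if first else total + counts
        first = False
    metrics = detection_metrics(total)

    # paired vertebrae
    err_records: list[LandmarkErrorRecord] = []
    ratios_pred: dict[str, list[float]] = {n: [] for n in RATIO_NAMES}
    ratios_ref: dict[str, list[float]] = {n: [] for n in RATIO_NAMES}
    bins: list[str] = []
    discrepancies: list[dict] = []
    for key in sorted(set(ref_by_key) & set(pred_by_key)):
        ref, pred = ref_by_key[key], pred_by_key[key]
        ref_m = measure(ref.landmarks)
        pred_m = measure(pred.landmarks)
        rec = landmark_errors(
            pred.landmarks, ref.landmarks,
            vertebra_id=f"{key[0]}/{key[1]}",
            qm_bin=ref_m.qm_status, region=ref.region,
        )
        err_records.append(rec)
        for name, pv, rv in zip(RATIO_NAMES, pred_m.ratios, ref_m.ratios):
            ratios_pred[name].append(pv)
            ratios_ref[name].append(rv)
        bins.append(ref_m.qm_status)
        flagged, offending = flag_discrepancy(
            pred_m.ratios, ref_m.ratios, discrepancy_threshold
        )
        if flagged:
            discrepancies.append(
                {"vertebra_id": rec.vertebra_id, "ratios": offending}
            )

    by_region = {
        reg: _summarize_errors([r for r in err_records if r.region == reg])
        for reg in ("thoracic", "lumbar")
    }
    by_bin = {
        qb: _summarize_errors([r for r in err_records if r.qm_bin == qb])
        for qb in dict.fromkeys(bins)
    }

    n_paired = len(bins)
    correlations, agreement = {}, {}
    for name in RATIO_NAMES:
        if n_paired >= 4:
            correlations[name] = correlation(
                ratios_pred[name], ratios_ref[name], alpha=alpha
            )
        if n_paired >= 2:
            agreement[name] = bland_altman(
                ratios_pred[name], ratios_ref[name], qm_bins=bins
            )

    return {
        "detection": {"counts": total, "metrics": metrics},
        "landmark_errors": {
            "overall": _summarize_errors(err_records),
            "by_region": by_region,
            "by_qm_bin": by_bin,
        },
        "correlations": correlations,
        "bland_altman": agreement,
        "discrepancies": {
            "threshold": discrepancy_threshold,
            "n_flagged": len(discrepancies),
            "fraction": (len(discrepancies) / n_paired) if n_paired else 0.0,
            "flagged": discrepancies,
        },
        "n_paired": n_paired,
        "n_reference_missing_prediction": len(set(ref_by_key) - set(pred_by_key)),
    }
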