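"""End-to-end orchestration: detect -> curve-filter -> crop -> landmarks
-> morphometry on one image.  Thin glue over the stage modules; every
stage remains individually usable."""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import landmark as _landmark
from . import morphometry as _morphometry
from . import segmentation as _segmentation
from . import spine_curve as _spine_curve
from .io import AnnotationRecord, RunConfig, get_logger
from .landmark import LandmarkSet
from .segmentation import CenterPoint, InstanceMask
from .spine_curve import CropWindow, SpinalCurve

__all__ = ["DetectionResult", "PipelineResult", "detect_centers", "run_pipeline"]


@dataclass(frozen=True)
class DetectionResult:
    """Stage-1 output: all detected centers, the fitted spinal curve, and
    the curve-filtered (retained) centers."""

    masks: list[InstanceMask]
    centers: list[CenterPoint]
    curve: SpinalCurve | None
    retained: list[CenterPoint]


@dataclass(frozen=True)
class PipelineResult:
    detection: DetectionResult
    windows: list[CropWindow]
    landmarks: list[LandmarkSet]  # image frame, one per retained center
    morphometry: list[_morphometry.VertebraMorphometry]


def detect_centers(
    image: np.ndarray,
    config: RunConfig | None = None,
    detector: Callable | None = None,
) -> DetectionResult:
    """Detect vertebral centers and reject off-curve false positives.

    With fewer than two detections no curve can be fitted; everything
    found is retained and ``curve`` is None.
    """
    cfg = config or RunConfig()
    log = get_logger(cfg.log_level)
    t0 = time.perf_counter()
    masks = _segmentation.segment_vertebrae(image, backend=detector)
    centers = [
        _segmentation.CenterPoint(c.x, c.y, source_mask_index=i)
        for i, m in enumerate(masks)
        for c in [_segmentation.mask_centroid(m)]
    ]
    if len(centers) < 2:
        log.debug("detection: %d centers, no curve fit", len(centers))
        return DetectionResult(masks, centers, None, list(centers))
    curve = _spine_curve.fit_spinal_curve(
        centers,
        max_degree=cfg.max_degree,
        residual_threshold=cfg.residual_threshold,
        n_iter=cfg.n_iter,
        seed=cfg.seed,
    )
    retained = _spine_curve.filter_centers(centers, curve)
    log.debug(
        "detection: %d masks, %d retained after curve filter (%.3f s)",
        len(masks), len(retained), time.perf_counter() - t0,
    )
    return DetectionResult(masks, centers, curve, retained)


def run_pipeline(
    image: np.ndarray,
    landmark_backend: Callable,
    config: RunConfig | None = None,
    detector: Callable | None = None,
) -> PipelineResult:
    """Run the full two-stage measurement on one image."""
    cfg = config or RunConfig()
    det = detect_centers(image, cfg, detector=detector)
    windows: list[CropWindow] = []
    landmark_sets: list[LandmarkSet] = []
    morph = []
    for center in det.retained:
        crop, window = _spine_curve.crop_vertebra(image, center, side=cfg.crop_side)
        lms_crop = _landmark.predict_landmarks(crop, window, landmark_backend)
        lms = _landmark.to_image_coords(lms_crop, window)
        windows.append(window)
        landmark_sets.append(lms)
        morph.append(_morphometry.measure(lms))
    return PipelineResult(
        detection=det, windows=windows, landmarks=landmark_sets, morphometry=morph
    )


def pipeline_records(
    result: PipelineResult,
    case_id: str = "run",
    image_id: str = "image-000",
    evaluator: str = "algorithm",
) -> list[AnnotationRecord]:
    """Package pipeline landmarks as annotation records (levels assigned
    cranial to caudal as V1.. when the backend provides none)."""
    records = []
    for i, lms in enumerate(result.landmarks):
        records.append(
            AnnotationRecord(
                case_id=case_id,
                image_id=image_id,
                level=lms.level or f"V{i + 1}",
                evaluator=evaluator,
                landmarks=lms,
            )
        )
    return records
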