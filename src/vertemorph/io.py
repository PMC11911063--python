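"""File formats, run configuration and logging shared by all stages.

The canonical annotation format is JSON (nested six-point records with
evaluator tags); CSV is a flat convenience export parsed by header name.
All coordinates are stored in image pixels, 0-based, origin top-left;
physical pixel spacing is carried as metadata only — the height ratios are
unit-free.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .errors import IOFormatError, SchemaError, ValidationError
from .landmark import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "SCHEMA_VERSION",
    "AnnotationRecord",
    "read_annotations",
    "write_annotations",
    "read_image",
    "write_image",
    "RunConfig",
    "get_logger",
]

SCHEMA_VERSION = "1"

logger = logging.getLogger("vertemorph")


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger writing to stderr (per-stage timing at DEBUG)."""
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)
    return logger


def region_of_level(level: str) -> str:
    return "thoracic" if str(level).upper().startswith("T") else "lumbar"


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated vertebra: identity plus its six named landmarks."""

    case_id: str
    image_id: str
    level: str
    evaluator: str
    landmarks: LandmarkSet
    region: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region is None:
            object.__setattr__(self, "region", region_of_level(self.level))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.image_id, self.level, self.evaluator)


def _records_to_obj(records: Sequence[AnnotationRecord]) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "records": [
            {
                "case_id": r.case_id,
                "image_id": r.image_id,
                "region": r.region,
                "level": r.level,
                "evaluator": r.evaluator,
                "landmarks": {n: list(getattr(r.landmarks, n)) for n in LANDMARK_NAMES},
                **({"extra": r.extra} if r.extra else {}),
            }
            for r in records
        ],
    }


def _record_from_obj(obj: dict) -> AnnotationRecord:
    for req in ("image_id", "level", "landmarks"):
        if req not in obj:
            raise SchemaError(f"annotation record missing field {req!r}: {obj}")
    lm_obj = obj["landmarks"]
    missing = [n for n in LANDMARK_NAMES if n not in lm_obj]
    if missing:
        raise SchemaError(
            f"record image_id={obj['image_id']!r} level={obj['level']!r} "
            f"missing landmarks: {missing}"
        )
    lms = LandmarkSet.from_dict(lm_obj, frame="image", level=obj["level"])
    return AnnotationRecord(
        case_id=str(obj.get("case_id", "")),
        image_id=str(obj["image_id"]),
        level=str(obj["level"]),
        evaluator=str(obj.get("evaluator", "")),
        landmarks=lms,
        region=obj.get("region"),
        extra=dict(obj.get("extra", {})),
    )


_CSV_FIXED = ("case_id", "image_id", "region", "level", "evaluator")


def write_annotations(
    records: Sequence[AnnotationRecord], path: str | Path
) -> Path:
    """Write annotations as JSON (canonical) or CSV (flat) by extension.

    CSV coordinates are written with six decimals; JSON keeps full float
    precision.  Unknown per-record fields survive the JSON round trip in
    ``extra``.
    """
    path = Path(path)
    try:
        if path.suffix.lower() == ".csv":
            with open(path, "w", newline="") as fh:
                names = [f"{n}_{ax}" for n in LANDMARK_NAMES for ax in ("x", "y")]
                writer = csv.writer(fh)
                writer.writerow(list(_CSV_FIXED) + names)
                for r in records:
                    coords = [
                        f"{v:.6f}"
                        for n in LANDMARK_NAMES
                        for v in getattr(r.landmarks, n)
                    ]
                    writer.writerow(
                        [r.case_id, r.image_id, r.region, r.level, r.evaluator]
                        + coords
                    )
        else:
            with open(path, "w") as fh:
                json.dump(_records_to_obj(records), fh, indent=1)
    except OSError as exc:
        raise IOFormatError(f"cannot write annotations to {path}: {exc}") from exc
    return path


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation file (JSON or CSV by extension)."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"annotation file not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_annotations_csv(path)
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise IOFormatError(f"cannot parse annotation JSON {path}: {exc}") from exc
    if "records" not in obj:
        raise SchemaError(f"{path}: missing top-level 'records' list")
    return [_record_from_obj(rec) for rec in obj["records"]]


def _read_annotations_csv(path: Path) -> list[AnnotationRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pts = {}
            for n in LANDMARK_NAMES:
                xk, yk = f"{n}_x", f"{n}_y"
                if row.get(xk) in (None, "") or row.get(yk) in (None, ""):
                    raise SchemaError(
                        f"{path}: record image_id={row.get('image_id')!r} "
                        f"level={row.get('level')!r} missing landmark {n!r}"
                    )
                pts[n] = (float(row[xk]), float(row[yk]))
            lms = LandmarkSet.from_dict(pts, frame="image", level=row.get("level"))
            records.append(
                AnnotationRecord(
                    case_id=row.get("case_id", ""),
                    image_id=row.get("image_id", ""),
                    level=row.get("level", ""),
                    evaluator=row.get("evaluator", ""),
                    landmarks=lms,
                    region=row.get("region") or None,
                )
            )
    return records


# --------------------------------------------------------------------------
# Images
# --------------------------------------------------------------------------

def read_image(path: str | Path) -> tuple[np.ndarray, tuple[float, float]]:
    """Read a grayscale radiograph from PNG, TIFF or DICOM.

    Returns (intensity array, (row_spacing, col_spacing) in mm).  DICOM
    rescale slope/intercept is applied; when no spacing metadata exists,
    unit spacing is returned with a warning.  Multichannel rasters are
    averaged to one channel.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".dcm", ".dicom"):
            import pydicom

            ds = pydicom.dcmread(path)
            arr = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
            spacing = getattr(ds, "PixelSpacing", None) or getattr(
                ds, "ImagerPixelSpacing", None
            )
            if spacing is not None:
                spacing = (float(spacing[0]), float(spacing[1]))
        elif suffix in (".png", ".tif", ".tiff"):
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path), dtype=float)
            spacing = None
        else:
            raise IOFormatError(
                f"unsupported image format {suffix!r} for {path} "
                "(expected PNG, TIFF or DICOM)"
            )
    except IOFormatError:
        raise
    except Exception as exc:
        raise IOFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise IOFormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if spacing is None:
        logger.warning("%s: no pixel-spacing metadata; assuming 1 mm", path)
        spacing = (1.0, 1.0)
    return arr, spacing


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a grayscale raster as 16-bit PNG or TIFF."""
    import imageio.v3 as iio

    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0, 65535).astype(np.uint16)
    try:
        iio.imwrite(path, arr)
    except OSError as exc:
        raise IOFormatError(f"cannot write image to {path}: {exc}") from exc
    return path


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of a pipeline run; every field has a documented default.

    tau_factor: detection matching radius as a fraction of the local
    reference vertebral height.  residual_threshold None means the
    scale-free default (half the median nearest-neighbor center spacing).
    """

    detector_backend: str = "ref"
    landmark_backend: str = "oracle"
    landmark_noise_sd: float = 0.0
    max_degree: int = 4
    residual_threshold: float | None = None
    n_iter: int = 500
    crop_side: int = 224
    tau_factor: float = 0.5
    discrepancy_threshold: float = 0.2
    alpha: float = 0.05
    anterior_side: str = "left"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.crop_side <= 0 or self.tau_factor <= 0:
            raise ValidationError("crop_side and tau_factor must be positive")
        if not 1 <= self.max_degree <= 4:
            raise ValidationError("max_degree must be in 1..4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        try:
            with open(path) as fh:
                obj = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise IOFormatError(f"cannot read config {path}: {exc}") from exc
        unknown = set(obj) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {
            "tool": "vertemorph",
            "version": __version__,
            "config_sha256": self.config_hash(),
            "seed": self.seed,
        }
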