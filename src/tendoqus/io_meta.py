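"""Image and subject-table I/O.

Images are plain single-channel 8-bit PNG or TIFF files; physical
metadata (pixel spacing in mm, scan view, subject identity) travels in a
JSON sidecar with the same basename and a ``.json`` extension rather
than in image tags, so any raster tool can open the pixel data
unchanged.  Subject-level tabular data (demographics, exclusion flags,
sheath measurements, per-view ROI statistics, reference labels) is a
CSV with a documented header.

Pixel convention used throughout the package: 0-based ``(row, col)``
coordinates, pixel centers at integer coordinates, and the physical
position of pixel ``(r, c)`` is ``(r * spacing_row, c * spacing_col)``
millimetres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from ._exceptions import (
    ImageFormatError,
    MetadataError,
    TableParseError,
    TableSchemaError,
)

VIEWS = ("transverse", "longitudinal")
LABELS = ("pos", "neg", "unknown")

#: Mandatory columns of a subject CSV, in no particular order.
SUBJECT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "weight_kg",
    "height_cm",
    "duration_wk",
    "tear_or_rupture",
    "prior_injection",
    "fracture_or_surgery",
    "reference_label",
)

#: Optional per-view ROI statistic columns (transverse/longitudinal).
STAT_COLUMNS = ("t_min", "t_max", "t_mean", "t_sd", "l_min", "l_max", "l_mean", "l_sd")

#: Optional sheath / fluid / Doppler criteria columns.
CRITERIA_COLUMNS = (
    "t_sheath_mm",
    "l_sheath_mm",
    "fluid_mm",
    "fluid_displaceable",
    "fluid_compressible",
    "color_flow",
)

#: Exclusion flags in the accounting order used when several are set.
EXCLUSION_ORDER = ("tear_or_rupture", "prior_injection", "fracture_or_surgery")


@dataclass
class ImageRecord:
    """A grayscale B-mode frame plus its physical metadata.

    Attributes
    ----------
    pixels:
        2-D ``uint8`` array, row-major, intensities in [0, 255]
        (0 = black, 255 = white).
    spacing_mm:
        ``(row, col)`` millimetres per pixel; both strictly positive.
    view:
        ``"transverse"`` or ``"longitudinal"``.
    subject_id:
        Free-form subject identifier.
    sex:
        ``"F"``/``"M"`` or ``None`` when unknown.
    group_label:
        Reference diagnosis group: ``"pos"``, ``"neg"`` or ``"unknown"``.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    view: str
    subject_id: str = ""
    sex: Optional[str] = None
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImageFormatError("pixel grid must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > 255:
                raise ImageFormatError(
                    f"pixel values outside [0, 255]: min={lo}, max={hi}"
                )
            if not np.issubdtype(self.pixels.dtype, np.integer):
                raise ImageFormatError("pixel values must be integers")
            self.pixels = self.pixels.astype(np.uint8)
        sr, sc = (float(s) for s in self.spacing_mm)
        if not (math.isfinite(sr) and math.isfinite(sc) and sr > 0 and sc > 0):
            raise MetadataError(f"spacing_mm must be finite and positive, got {self.spacing_mm}")
        self.spacing_mm = (sr, sc)
        if self.view not in VIEWS:
            raise MetadataError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.sex not in (None, "F", "M"):
            raise MetadataError(f"sex must be 'F', 'M' or None, got {self.sex!r}")
        if self.group_label not in LABELS:
            raise MetadataError(f"group_label must be one of {LABELS}, got {self.group_label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SheathMeasurements:
    """Tendon-sheath findings feeding the rule-based reference criteria.

    All thicknesses/depths in millimetres; ``None`` marks a measurement
    that was not taken.
    """

    transverse_sheath_mm: Optional[float] = None
    longitudinal_sheath_mm: Optional[float] = None
    fluid_depth_mm: Optional[float] = None
    fluid_displaceable: bool = False
    fluid_compressible: bool = False
    color_flow_increased: bool = False
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("transverse_sheath_mm", "longitudinal_sheath_mm", "fluid_depth_mm"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise MetadataError(f"{name} must be >= 0 when present, got {v}")


@dataclass
class SubjectRecord:
    """One row of the subject table."""

    subject_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    duration_wk: Optional[float] = None
    tear_or_rupture: bool = False
    prior_injection: bool = False
    fracture_or_surgery: bool = False
    reference_label: str = "unknown"
    roi_stats: dict = field(default_factory=dict)  # view -> ROIStats-like
    sheath: Optional[SheathMeasurements] = None


def _load_sidecar(sidecar_path) -> dict:
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise MetadataError(f"sidecar not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    if "spacing_mm" not in meta:
        raise MetadataError(f"sidecar {sidecar_path} lacks 'spacing_mm'")
    if "view" not in meta:
        raise MetadataError(f"sidecar {sidecar_path} lacks 'view'")
    return meta


def read_image(image_path, sidecar_path=None) -> ImageRecord:
    """Read an 8-bit grayscale PNG/TIFF and its JSON sidecar.

    Parameters
    ----------
    image_path:
        Path to a single-channel 8-bit PNG or TIFF.
    sidecar_path:
        Path to the JSON sidecar; defaults to the image path with a
        ``.json`` extension.

    Raises
    ------
    ImageFormatError
        When the image is multi-channel or deeper than 8 bits.
    MetadataError
        When the sidecar is missing, unparseable or lacks
        ``spacing_mm``/``view``, or spacing is non-positive.
    """
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".json")
    meta = _load_sidecar(sidecar_path)

    with Image.open(image_path) as img:
        if img.mode != "L":
            raise ImageFormatError(
                f"{image_path}: expected single-channel 8-bit image (mode 'L'), got mode {img.mode!r}"
            )
        pixels = np.asarray(img, dtype=np.uint8)

    spacing = meta["spacing_mm"]
    if not isinstance(spacing, Sequence) or len(spacing) != 2:
        raise MetadataError(f"spacing_mm must be [row, col], got {spacing!r}")
    return ImageRecord(
        pixels=pixels,
        spacing_mm=(float(spacing[0]), float(spacing[1])),
        view=meta["view"],
        subject_id=str(meta.get("subject_id", "")),
        sex=meta.get("sex"),
        group_label=meta.get("group_label", "unknown"),
    )


def write_image(record: ImageRecord, image_path, sidecar_path=None) -> None:
    """Write an :class:`ImageRecord` as PNG/TIFF plus JSON sidecar."""
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".json")
    Image.fromarray(record.pixels, mode="L").save(image_path)
    meta = {
        "spacing_mm": list(record.spacing_mm),
        "view": record.view,
        "subject_id": record.subject_id,
        "group_label": record.group_label,
    }
    if record.sex is not None:
        meta["sex"] = record.sex
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in ("nan", "none"):
        return False
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise TableParseError(f"row {row}: column {column!r} has non-boolean value {value!r}")


def _parse_float(value, column: str, row: int) -> Optional[float]:
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "none", "na"):
        return None
    try:
        x = float(s)
    except ValueError as exc:
        raise TableParseError(f"row {row}: column {column!r} has non-numeric value {value!r}") from exc
    if x < 0:
        raise TableParseError(f"row {row}: column {column!r} must be non-negative, got {x}")
    return x


def read_subject_table(csv_path) -> list[SubjectRecord]:
    """Parse a subject CSV into :class:`SubjectRecord` objects.

    Mandatory columns are listed in :data:`SUBJECT_COLUMNS`; the
    optional ROI-statistic and criteria columns are picked up when
    present.  Unknown reference labels are preserved as ``"unknown"``.

    Raises
    ------
    TableSchemaError
        When a mandatory column is absent.
    TableParseError
        When a value cannot be parsed; the message names the 0-based
        data row.
    """
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{csv_path}: missing mandatory columns {missing}")

    has_stats = all(c in df.columns for c in STAT_COLUMNS)
    has_criteria = all(c in df.columns for c in CRITERIA_COLUMNS)

    records: list[SubjectRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        sex = row["sex"].strip() or None
        if sex not in (None, "F", "M"):
            raise TableParseError(f"row {i}: column 'sex' has invalid value {row['sex']!r}")
        label = row["reference_label"].strip() or "unknown"
        if label not in LABELS:
            raise TableParseError(
                f"row {i}: column 'reference_label' has invalid value {row['reference_label']!r}"
            )
        rec = SubjectRecord(
            subject_id=row["subject_id"],
            age=_parse_float(row["age"], "age", i),
            sex=sex,
            weight_kg=_parse_float(row["weight_kg"], "weight_kg", i),
            height_cm=_parse_float(row["height_cm"], "height_cm", i),
            duration_wk=_parse_float(row["duration_wk"], "duration_wk", i),
            tear_or_rupture=_parse_bool(row["tear_or_rupture"], "tear_or_rupture", i),
            prior_injection=_parse_bool(row["prior_injection"], "prior_injection", i),
            fracture_or_surgery=_parse_bool(row["fracture_or_surgery"], "fracture_or_surgery", i),
            reference_label=label,
        )
        if has_stats:
            for view, prefix in (("transverse", "t"), ("longitudinal", "l")):
                vals = {
                    k: _parse_float(row[f"{prefix}_{k}"], f"{prefix}_{k}", i)
                    for k in ("min", "max", "mean", "sd")
                }
                if all(v is not None for v in vals.values()):
                    rec.roi_stats[view] = vals
        if has_criteria:
            rec.sheath = SheathMeasurements(
                transverse_sheath_mm=_parse_float(row["t_sheath_mm"], "t_sheath_mm", i),
                longitudinal_sheath_mm=_parse_float(row["l_sheath_mm"], "l_sheath_mm", i),
                fluid_depth_mm=_parse_float(row["fluid_mm"], "fluid_mm", i),
                fluid_displaceable=_parse_bool(row["fluid_displaceable"], "fluid_displaceable", i),
                fluid_compressible=_parse_bool(row["fluid_compressible"], "fluid_compressible", i),
                color_flow_increased=_parse_bool(row["color_flow"], "color_flow", i),
                sex=sex,
            )
        records.append(rec)
    return records


def apply_exclusions(records: Sequence[SubjectRecord]) -> tuple[list[SubjectRecord], dict[str, int]]:
    """Drop subjects with any exclusion flag set.

    A subject is kept iff all three flags (tendon tear/rupture, recent
    local injection, fracture or prior surgery) are false.  A subject
    with several flags set is counted once, under the first flag in
    :data:`EXCLUSION_ORDER`.

    Returns
    -------
    (kept, report)
        ``kept`` is the retained subset in input order; ``report`` maps
        each exclusion reason to its count.
    """
    kept: list[SubjectRecord] = []
    report = {reason: 0 for reason in EXCLUSION_ORDER}
    for rec in records:
        for reason in EXCLUSION_ORDER:
            if getattr(rec, reason, False):
                report[reason] += 1
                break
        else:
            kept.append(rec)
    return kept, report
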