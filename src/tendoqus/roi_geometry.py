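"""Physical-area ROI rasterization.

The region of interest is specified in physical units (a target area in
mm², default 2.0) and rasterized onto the image lattice using the pixel
spacing: a closed disk for the transverse view, an axis-aligned square
block for the longitudinal view.  A pixel belongs to the circular ROI
iff its *center* lies within the disk (center-in-region rule); the
square block's side is rounded to the nearest whole number of pixels
per axis, so anisotropic spacing yields a physically square but
pixel-rectangular block.

The rasterized mask is advisory-checked against the protocol's size
constraints: the physical area should be 2 mm² (within 5%) and the
pixel count should exceed 2000, which at 2 mm² requires a spacing of
roughly 0.03 mm/px or finer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import GeometryError
from .io_meta import ImageRecord

DEFAULT_ROI_AREA_MM2 = 2.0
MIN_ROI_PIXELS = 2000
AREA_RELATIVE_TOLERANCE = 0.05

#: Conventional ROI shape per scan view.
SHAPE_FOR_VIEW = {"transverse": "circle", "longitudinal": "square"}


@dataclass
class ROISpec:
    """ROI specification in physical units.

    ``center`` is a (possibly fractional) ``(row, col)`` pixel
    coordinate; ``area_mm2`` is the target physical area.
    """

    shape: str
    center: tuple[float, float]
    area_mm2: float = DEFAULT_ROI_AREA_MM2

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise GeometryError(f"shape must be 'circle' or 'square', got {self.shape!r}")
        if not (math.isfinite(self.area_mm2) and self.area_mm2 > 0):
            raise GeometryError(f"area_mm2 must be positive, got {self.area_mm2}")
        self.center = (float(self.center[0]), float(self.center[1]))


@dataclass
class PixelMask:
    """Explicit list of ROI pixels with the achieved physical area."""

    coords: np.ndarray  # (n, 2) int array of (row, col)
    achieved_area_mm2: float
    n_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 2)
        self.n_pixels = len(self.coords)

    @property
    def rows(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.coords[:, 1]


def _nearest_int_tie_low(x: float) -> int:
    """Nearest integer, breaking exact .5 ties toward the smaller value."""
    f = math.floor(x)
    return f if (x - f) <= 0.5 else f + 1


def _check_view_shape(spec: ROISpec, view: str) -> None:
    expected = SHAPE_FOR_VIEW.get(view)
    if expected is not None and spec.shape != expected:
        warnings.warn(
            f"ROI shape {spec.shape!r} is unconventional for the {view} view "
            f"(protocol uses {expected!r})",
            stacklevel=3,
        )


def roi_pixel_mask(spec: ROISpec, image: ImageRecord) -> PixelMask:
    """Rasterize an :class:`ROISpec` onto an image's pixel lattice.

    Circle: pixel (r, c) is included iff the Euclidean distance from
    its center to ``spec.center``, measured in millimetres, is at most
    ``radius = sqrt(area_mm2 / pi)`` (closed disk).  Square: an
    axis-aligned block of ``round(sqrt(area_mm2) / spacing)`` pixels
    per axis, placed so its centroid is nearest ``spec.center`` (ties
    toward smaller indices).

    Raises
    ------
    GeometryError
        When any included pixel would fall outside the image bounds
        (no silent clipping), or the center lies outside the image.
    """
    nrow, ncol = image.shape
    sr, sc = image.spacing_mm
    cr, cc = spec.center
    if not (0 <= cr <= nrow - 1 and 0 <= cc <= ncol - 1):
        raise GeometryError(f"ROI center {spec.center} outside image of shape {image.shape}")
    _check_view_shape(spec, image.view)

    if spec.shape == "circle":
        radius = math.sqrt(spec.area_mm2 / math.pi)
        r_lo = math.floor(cr - radius / sr)
        r_hi = math.ceil(cr + radius / sr)
        c_lo = math.floor(cc - radius / sc)
        c_hi = math.ceil(cc + radius / sc)
        rr, cols = np.meshgrid(
            np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1), indexing="ij"
        )
        dist2 = ((rr - cr) * sr) ** 2 + ((cols - cc) * sc) ** 2
        inside = dist2 <= radius**2 + 1e-12
        coords = np.column_stack([rr[inside], cols[inside]])
        if coords.size == 0:
            # Closed-disk rule guarantees at least the nearest pixel when
            # the center sits exactly on it; otherwise a sub-pixel disk
            # may miss every pixel center.
            raise GeometryError(
                f"circular ROI of area {spec.area_mm2} mm2 contains no pixel centers"
            )
    else:
        side_mm = math.sqrt(spec.area_mm2)
        side_r = max(1, _nearest_int_tie_low(side_mm / sr))
        side_c = max(1, _nearest_int_tie_low(side_mm / sc))
        r0 = _nearest_int_tie_low(cr - (side_r - 1) / 2.0)
        c0 = _nearest_int_tie_low(cc - (side_c - 1) / 2.0)
        rr, cols = np.meshgrid(
            np.arange(r0, r0 + side_r), np.arange(c0, c0 + side_c), indexing="ij"
        )
        coords = np.column_stack([rr.ravel(), cols.ravel()])

    out = (
        (coords[:, 0] < 0)
        | (coords[:, 0] >= nrow)
        | (coords[:, 1] < 0)
        | (coords[:, 1] >= ncol)
    )
    if out.any():
        raise GeometryError(
            f"ROI extends beyond image bounds: {int(out.sum())} of {len(coords)} "
            f"pixels outside a {nrow}x{ncol} image"
        )
    return PixelMask(coords=coords, achieved_area_mm2=len(coords) * sr * sc)


def validate_roi(mask: PixelMask, target_area_mm2: float = DEFAULT_ROI_AREA_MM2) -> list[str]:
    """Advisory checks of the protocol's ROI size constraints.

    Returns a list of human-readable warnings; empty when the mask has
    more than 2000 pixels and its achieved area is within 5% of the
    target.  Never raises: the constraints are advisory.
    """
    problems = []
    if mask.n_pixels <= MIN_ROI_PIXELS:
        problems.append(
            f"ROI has {mask.n_pixels} pixels; the protocol calls for more than "
            f"{MIN_ROI_PIXELS} (use finer pixel spacing)"
        )
    rel = abs(mask.achieved_area_mm2 - target_area_mm2) / target_area_mm2
    if rel > AREA_RELATIVE_TOLERANCE:
        problems.append(
            f"achieved ROI area {mask.achieved_area_mm2:.4f} mm2 deviates "
            f"{100 * rel:.1f}% from the {target_area_mm2} mm2 target"
        )
    return problems


def centered_roi_spec(image: ImageRecord, area_mm2: float = DEFAULT_ROI_AREA_MM2) -> ROISpec:
    """ROI of the conventional shape for the image's view, at its center."""
    nrow, ncol = image.shape
    return ROISpec(
        shape=SHAPE_FOR_VIEW[image.view],
        center=((nrow - 1) / 2.0, (ncol - 1) / 2.0),
        area_mm2=area_mm2,
    )
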