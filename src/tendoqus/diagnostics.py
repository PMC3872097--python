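"""Reference labeling and cut-off classification.

Two diagnostic routes live here.  The *reference* route applies the
rule-based sonographic criteria used to define ground truth: sex-
specific tendon-sheath swelling thresholds (transverse >= 4.6 mm for
women / 5.5 mm for men; longitudinal >= 2.5 / 2.8 mm), or displaceable
and compressible sheath-fluid accumulation of at least 3 mm — in
either case with increased Doppler color flow around the tendon, which
is treated as essential and AND-ed with the structural findings.  The
*quantitative* route compares the ROI StdDev against a per-view
cut-off (strictly greater than, i.e. the score must surpass it), the
calibrated operating points being 26.85 for the transverse and 21.25
for the longitudinal view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._exceptions import LabelingError, TendoQusError
from .echotexture import ROIStats
from .io_meta import SheathMeasurements

#: Sex-specific sheath-swelling thresholds (mm), inclusive.
SWELLING_THRESHOLDS_MM = {
    "F": {"transverse": 4.6, "longitudinal": 2.5},
    "M": {"transverse": 5.5, "longitudinal": 2.8},
}

FLUID_DEPTH_THRESHOLD_MM = 3.0

#: Calibrated per-view StdDev cut-offs.
DEFAULT_CUTOFFS = {"transverse": 26.85, "longitudinal": 21.25}

COMBINATION_RULES = ("any_view", "transverse_only", "longitudinal_only")


@dataclass
class CutoffModel:
    """Per-view decision threshold; scores strictly above it are positive."""

    view: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.view not in ("transverse", "longitudinal"):
            raise TendoQusError(f"unknown view {self.view!r}")
        if not self.cutoff > 0:
            raise TendoQusError(f"cutoff must be positive, got {self.cutoff}")

    @classmethod
    def default(cls, view: str) -> "CutoffModel":
        return cls(view=view, cutoff=DEFAULT_CUTOFFS[view])


def criteria_label(m: SheathMeasurements, require_color_flow: bool = True) -> str:
    """Apply the rule-based reference criteria to one subject.

    Positive iff (sheath swelling at the sex-specific threshold OR
    qualifying sheath fluid) AND increased color flow.  Swelling and
    fluid thresholds are inclusive (``>=``).  ``require_color_flow``
    relaxes the Doppler requirement when set to ``False``.

    Raises
    ------
    LabelingError
        When sex is unknown or no measurement is available.
    """
    if m.sex not in SWELLING_THRESHOLDS_MM:
        raise LabelingError(f"sex must be 'F' or 'M' to evaluate the criteria, got {m.sex!r}")
    if (
        m.transverse_sheath_mm is None
        and m.longitudinal_sheath_mm is None
        and m.fluid_depth_mm is None
    ):
        raise LabelingError("no sheath or fluid measurement available")

    thr = SWELLING_THRESHOLDS_MM[m.sex]
    swelling = False
    if m.transverse_sheath_mm is not None:
        swelling = swelling or m.transverse_sheath_mm >= thr["transverse"]
    if m.longitudinal_sheath_mm is not None:
        swelling = swelling or m.longitudinal_sheath_mm >= thr["longitudinal"]

    fluid = (
        m.fluid_depth_mm is not None
        and m.fluid_depth_mm >= FLUID_DEPTH_THRESHOLD_MM
        and m.fluid_displaceable
        and m.fluid_compressible
    )

    structural = swelling or fluid
    if require_color_flow:
        return "pos" if (structural and m.color_flow_increased) else "neg"
    return "pos" if structural else "neg"


def classify_quantitative(stats: ROIStats, model: CutoffModel) -> str:
    """Positive iff the ROI StdDev strictly surpasses the view's cut-off."""
    if stats.view != model.view:
        raise TendoQusError(
            f"view mismatch: stats are {stats.view!r} but the cutoff model is {model.view!r}"
        )
    return "pos" if stats.stddev > model.cutoff else "neg"


def classify_subject(
    stats_by_view: Mapping[str, ROIStats],
    models_by_view: Mapping[str, CutoffModel],
    rule: str = "any_view",
) -> str:
    """Combine per-view cut-off decisions into one subject-level label.

    ``any_view`` (default) is positive when either available view
    fires; the single-view rules use only that view and fail when it
    is absent.
    """
    if rule not in COMBINATION_RULES:
        raise TendoQusError(f"rule must be one of {COMBINATION_RULES}, got {rule!r}")
    if not stats_by_view:
        raise TendoQusError("no view available to classify")

    if rule == "any_view":
        views = list(stats_by_view)
    else:
        view = rule.removesuffix("_only")
        if view not in stats_by_view:
            raise TendoQusError(f"rule {rule!r} but the {view} view is absent")
        views = [view]

    decisions = []
    for view in views:
        model = models_by_view.get(view)
        if model is None:
            raise TendoQusError(f"no cutoff model for view {view!r}")
        decisions.append(classify_quantitative(stats_by_view[view], model))
    return "pos" if "pos" in decisions else "neg"
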