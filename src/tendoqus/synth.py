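"""Synthetic cohorts and B-mode-like tendon images.

The diagnostic method consumes only first-order ROI statistics, so the
generator targets the first two moments of the ROI intensity
distribution rather than physical acoustics.  Two layers:

* :func:`simulate_scores` draws per-subject, per-view ROI StdDev
  values from the published group distributions (a binormal model:
  transverse 30.1 ± 6.8 tendinitis vs 21.9 ± 4.1 non-tendinitis;
  longitudinal 26.5 ± 6.0 vs 18.7 ± 4.7; 136 vs 200 subjects).

* :func:`simulate_tendon_image` renders an image whose centered 2 mm²
  ROI realizes a requested (mean, StdDev) target.  The ROI intensity
  distribution is a three-component mixture: baseline Gaussian speckle
  around the tendon's mean echogenicity (with a sinusoidal fibrillar
  band modulation in the longitudinal view), a hypoechoic "fluid"
  component (sheath effusion) and a hyperechoic component (condensed
  fibers).  The two component fractions are solved in closed form from
  the two mixture-moment equations; spatially, fluid pixels form one
  or two contiguous blobs abutting the ROI margin and hyperechoic
  pixels form fiber-direction streaks, so images look tendon-like
  while the per-pixel mixture identity stays valid.

Tendinitis raises the StdDev (heterogeneity), raises the maximum and
lowers the minimum while leaving the mean roughly unchanged, matching
the published group contrasts.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._exceptions import InfeasibleMixtureError, ParameterError
from .diagnostics import FLUID_DEPTH_THRESHOLD_MM, SWELLING_THRESHOLDS_MM
from .io_meta import ImageRecord, write_image
from .roi_geometry import ROISpec, centered_roi_spec, roi_pixel_mask

#: Published per-group ROI mean intensities, used as image targets.
GROUP_MEAN_TARGETS = {
    "transverse": {"pos": 112.4, "neg": 111.8},
    "longitudinal": {"pos": 102.9, "neg": 94.2},
}

#: Whole-cohort mean intensity per view, used as the baseline speckle mean.
VIEW_BASELINE_MEAN = {"transverse": 112.0, "longitudinal": 97.7}

#: Per-group demographic distributions (mean, sd) for the study generator.
GROUP_DEMOGRAPHICS = {
    "pos": {"age": (53.8, 11.9), "weight_kg": (59.1, 11.2), "height_cm": (160.7, 7.4), "duration_wk": (11.7, 9.4)},
    "neg": {"age": (52.2, 14.3), "weight_kg": (60.0, 12.3), "height_cm": (161.6, 8.4), "duration_wk": (10.4, 9.6)},
}
GROUP_MALE_FRACTION = {"pos": 0.397, "neg": 0.410}

#: Fraction of subjects whose criteria fields contradict the group label,
#: emulating equivocal cases.
EQUIVOCAL_FRACTION = 0.05


@dataclass
class CohortParams:
    """Binormal per-view StdDev score model of the two study groups.

    Each pair is (mean, sd) of the ROI StdDev statistic; ``n_pos`` and
    ``n_neg`` are the group sizes.
    """

    transverse_pos: tuple[float, float] = (30.1, 6.8)
    transverse_neg: tuple[float, float] = (21.9, 4.1)
    longitudinal_pos: tuple[float, float] = (26.5, 6.0)
    longitudinal_neg: tuple[float, float] = (18.7, 4.7)
    n_pos: int = 136
    n_neg: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transverse_pos", "transverse_neg", "longitudinal_pos", "longitudinal_neg"):
            mu, sd = getattr(self, name)
            if not (math.isfinite(mu) and math.isfinite(sd) and sd > 0):
                raise ParameterError(f"{name} must have finite mean and sd > 0, got {(mu, sd)}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ParameterError("group sizes must be at least 1")

    def group(self, view: str, condition: str) -> tuple[float, float]:
        return getattr(self, f"{view}_{condition}")


@dataclass
class TextureParams:
    """Intensity model of the synthetic ROI texture.

    ``baseline_mean`` is the mean echogenicity of the tendon speckle
    (0–255 scale); ``speckle_sd`` its per-pixel standard deviation,
    shared by all three components.  ``band_amplitude``/``band_period_mm``
    describe the sinusoidal fibrillar stripe modulation (applied in the
    longitudinal view).  ``fluid_mean`` and ``hyper_mean`` are the
    hypoechoic and hyperechoic component means.  When
    ``fluid_fraction``/``hyper_fraction`` are set they override the
    moment-matching solution.
    """

    baseline_mean: float = 112.0
    speckle_sd: float = 8.0
    band_amplitude: float = 0.0
    band_period_mm: float = 0.4
    fluid_mean: float = 45.0
    hyper_mean: float = 200.0
    fluid_fraction: Optional[float] = None
    hyper_fraction: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("baseline_mean", "fluid_mean", "hyper_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ParameterError(f"{name} must be in [0, 255], got {v}")
        if self.speckle_sd <= 0:
            raise ParameterError("speckle_sd must be positive")
        if self.band_amplitude < 0 or self.band_period_mm <= 0:
            raise ParameterError("band parameters must be non-negative / positive")
        ff = self.fluid_fraction or 0.0
        fh = self.hyper_fraction or 0.0
        if ff < 0 or fh < 0 or ff + fh > 1.0:
            raise ParameterError("fractions must be >= 0 and sum to at most 1")


def default_texture(view: str) -> TextureParams:
    """Per-view texture defaults: fibrillar bands only in the longitudinal view."""
    if view == "longitudinal":
        return TextureParams(
            baseline_mean=VIEW_BASELINE_MEAN["longitudinal"],
            band_amplitude=6.0,
            band_period_mm=0.4,
        )
    return TextureParams(baseline_mean=VIEW_BASELINE_MEAN["transverse"])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, size, lo=0.0, hi=255.0) -> np.ndarray:
    """Normal draws with out-of-range values redrawn."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ParameterError(f"truncated normal ({mean}, {sd}) cannot stay within [{lo}, {hi}]")


def simulate_scores(params: CohortParams) -> pd.DataFrame:
    """Draw per-subject per-view StdDev scores for a two-group cohort.

    Returns a DataFrame with columns ``subject_id``, ``group_label``,
    ``t_sd`` and ``l_sd``; draws are truncated to [0, 255] by redraw
    and deterministic given ``params.seed``.
    """
    rng = _rng(params.seed)
    rows = []
    for condition, n in (("pos", params.n_pos), ("neg", params.n_neg)):
        t = _truncated_normal(rng, *params.group("transverse", condition), n)
        l = _truncated_normal(rng, *params.group("longitudinal", condition), n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{condition}{i + 1:04d}",
                    "group_label": condition,
                    "t_sd": t[i],
                    "l_sd": l[i],
                }
            )
    return pd.DataFrame(rows)


def _component_moments(texture: TextureParams, view: str) -> tuple[np.ndarray, np.ndarray]:
    """Means and second moments of the three mixture components.

    The sinusoidal band modulation adds A²/2 to the baseline variance
    (the ROI spans many periods, so the sine averages out of the mean).
    """
    var = texture.speckle_sd**2
    band_var = texture.band_amplitude**2 / 2.0 if view == "longitudinal" else 0.0
    means = np.array([texture.baseline_mean, texture.fluid_mean, texture.hyper_mean])
    variances = np.array([var + band_var, var, var])
    return means, variances + means**2


def moment_match_mixture(
    target_mean: float,
    target_sd: float,
    texture: TextureParams,
    view: str = "transverse",
) -> tuple[float, float]:
    """Solve the two mixture-moment equations for the component fractions.

    With ``f_base = 1 − f_fluid − f_hyper`` the mixture mean is
    ``Σ fᵢ μᵢ`` and the mixture second moment ``Σ fᵢ (σᵢ² + μᵢ²)``;
    setting these to the target mean and ``sd² + mean²`` is a 2×2
    linear system in the two fractions.

    Raises
    ------
    InfeasibleMixtureError
        When a fraction comes out negative or the fractions exceed 1;
        the message names the violated bound.
    """
    means, m2 = _component_moments(texture, view)
    target_m2 = target_sd**2 + target_mean**2
    # Unknowns (f_fluid, f_hyper); baseline contributes the constants.
    a = np.array(
        [
            [means[1] - means[0], means[2] - means[0]],
            [m2[1] - m2[0], m2[2] - m2[0]],
        ]
    )
    b = np.array([target_mean - means[0], target_m2 - m2[0]])
    try:
        f_fluid, f_hyper = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise InfeasibleMixtureError("degenerate component configuration") from exc
    tol = 1e-10
    if f_fluid < -tol:
        raise InfeasibleMixtureError(
            f"target ({target_mean}, {target_sd}) needs fluid_fraction {f_fluid:.4g} < 0"
        )
    if f_hyper < -tol:
        raise InfeasibleMixtureError(
            f"target ({target_mean}, {target_sd}) needs hyper_fraction {f_hyper:.4g} < 0"
        )
    if f_fluid + f_hyper > 1.0 + tol:
        raise InfeasibleMixtureError(
            f"target ({target_mean}, {target_sd}) needs fraction sum "
            f"{f_fluid + f_hyper:.4g} > 1"
        )
    return float(max(f_fluid, 0.0)), float(max(f_hyper, 0.0))


def feasible_sd_floor(texture: TextureParams, view: str) -> float:
    """Smallest ROI StdDev of the pure baseline texture (no extreme components)."""
    band_var = texture.band_amplitude**2 / 2.0 if view == "longitudinal" else 0.0
    return math.sqrt(texture.speckle_sd**2 + band_var)


def min_feasible_sd(target_mean: float, texture: TextureParams, view: str) -> float:
    """Smallest ROI StdDev achievable at a given target mean.

    Shifting the mixture mean away from the baseline requires a
    non-zero extreme-component fraction, which carries a variance
    floor; at the baseline mean the floor is the pure speckle StdDev.
    """
    means, m2 = _component_moments(texture, view)
    if target_mean >= means[0]:
        if target_mean > means[2]:
            raise InfeasibleMixtureError(
                f"target mean {target_mean} exceeds the hyper component mean {means[2]}"
            )
        f = (target_mean - means[0]) / (means[2] - means[0])
        second = (1.0 - f) * m2[0] + f * m2[2]
    else:
        if target_mean < means[1]:
            raise InfeasibleMixtureError(
                f"target mean {target_mean} is below the fluid component mean {means[1]}"
            )
        f = (means[0] - target_mean) / (means[0] - means[1])
        second = (1.0 - f) * m2[0] + f * m2[1]
    return math.sqrt(max(second - target_mean**2, 0.0))


def _match_with_clamp(
    target_mean: float, target_sd: float, texture: TextureParams, view: str
) -> tuple[float, float, float]:
    """Moment match, nudging an infeasible target StdDev toward feasibility.

    Returns (f_fluid, f_hyper, achieved_target_sd).  Draws below the
    mean-dependent variance floor are clamped up to it; pathologically
    large draws (fraction sum above 1) are walked down 5% at a time.
    """
    sd = max(target_sd, min_feasible_sd(target_mean, texture, view) + 0.3)
    for _ in range(60):
        try:
            ff, fh = moment_match_mixture(target_mean, sd, texture, view)
            return ff, fh, sd
        except InfeasibleMixtureError:
            sd *= 0.95
    raise InfeasibleMixtureError(
        f"no feasible StdDev near {target_sd} for mean {target_mean} ({view})"
    )


def _margin_anchor(coords: np.ndarray, center: tuple[float, float], theta: float) -> np.ndarray:
    """ROI pixel farthest along direction theta: a point on the ROI margin."""
    d = np.array([math.cos(theta), math.sin(theta)])
    proj = (coords - np.asarray(center)) @ d
    return coords[int(np.argmax(proj))]


def _assign_components(
    coords: np.ndarray,
    center: tuple[float, float],
    n_fluid: int,
    n_hyper: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick fluid-blob and hyper-streak pixel index sets within the ROI."""
    n = len(coords)
    taken = np.zeros(n, dtype=bool)
    idx = np.arange(n)

    fluid_idx = []
    if n_fluid > 0:
        n_blobs = 1 if n_fluid < 60 or rng.random() < 0.5 else 2
        sizes = [n_fluid] if n_blobs == 1 else [n_fluid // 2, n_fluid - n_fluid // 2]
        for size in sizes:
            anchor = _margin_anchor(coords, center, rng.uniform(0.0, 2.0 * math.pi))
            free = idx[~taken]
            d2 = ((coords[free] - anchor) ** 2).sum(axis=1)
            chosen = free[np.argsort(d2, kind="stable")[:size]]
            taken[chosen] = True
            fluid_idx.append(chosen)
    fluid_idx = np.concatenate(fluid_idx) if fluid_idx else np.empty(0, dtype=int)

    hyper_idx = np.empty(0, dtype=int)
    if n_hyper > 0:
        rows = coords[:, 0]
        r_lo, r_hi = rows.min(), rows.max()
        n_streaks = 1 if n_hyper < 120 else 2
        streak_rows = rng.uniform(r_lo + 1, r_hi - 1, n_streaks) if r_hi - r_lo > 2 else [center[0]]
        free = idx[~taken]
        dist = np.min(
            np.abs(rows[free][:, None] - np.asarray(streak_rows)[None, :]), axis=1
        )
        hyper_idx = free[np.argsort(dist, kind="stable")[:n_hyper]]
    return fluid_idx, hyper_idx


def simulate_tendon_image(
    view: str,
    condition: str,
    target: tuple[float, float],
    texture: Optional[TextureParams] = None,
    spacing_mm: tuple[float, float] = (0.02, 0.02),
    size_px: tuple[int, int] = (128, 128),
    seed=None,
) -> tuple[ImageRecord, ROISpec]:
    """Render a tendon-like image whose centered 2 mm² ROI hits a moment target.

    Parameters
    ----------
    view, condition:
        Scan view and intended group label (``pos``/``neg``).
    target:
        (mean, StdDev) the ROI statistics should realize.
    texture:
        Intensity model; per-view defaults when omitted.  Explicit
        ``fluid_fraction``/``hyper_fraction`` values bypass the moment
        match.
    seed:
        Any :func:`numpy.random.default_rng` seed, or a Generator.

    Returns the image and the ROI specification pointing at the
    calibrated region.
    """
    if condition not in ("pos", "neg"):
        raise ParameterError(f"condition must be 'pos' or 'neg', got {condition!r}")
    texture = texture if texture is not None else default_texture(view)
    rng = _rng(seed if seed is not None else texture.seed)
    target_mean, target_sd = float(target[0]), float(target[1])

    if texture.fluid_fraction is not None or texture.hyper_fraction is not None:
        f_fluid = texture.fluid_fraction or 0.0
        f_hyper = texture.hyper_fraction or 0.0
    else:
        f_fluid, f_hyper = moment_match_mixture(target_mean, target_sd, texture, view)

    nrow, ncol = size_px
    sr, sc = spacing_mm
    banded = view == "longitudinal" and texture.band_amplitude > 0
    field = rng.normal(texture.baseline_mean, texture.speckle_sd, (nrow, ncol))
    if banded:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        band = texture.band_amplitude * np.sin(
            2.0 * math.pi * np.arange(nrow) * sr / texture.band_period_mm + phase
        )
        field += band[:, None]

    # Build a placeholder record to rasterize the centered ROI.
    probe = ImageRecord(
        pixels=np.zeros((nrow, ncol), dtype=np.uint8),
        spacing_mm=spacing_mm,
        view=view,
        group_label=condition,
    )
    spec = centered_roi_spec(probe)
    mask = roi_pixel_mask(spec, probe)

    n_fluid = int(round(f_fluid * mask.n_pixels))
    n_hyper = int(round(f_hyper * mask.n_pixels))
    fluid_idx, hyper_idx = _assign_components(
        mask.coords, spec.center, n_fluid, n_hyper, rng
    )
    if len(fluid_idx):
        fr, fc = mask.coords[fluid_idx, 0], mask.coords[fluid_idx, 1]
        field[fr, fc] = rng.normal(texture.fluid_mean, texture.speckle_sd, len(fluid_idx))
    if len(hyper_idx):
        hr, hc = mask.coords[hyper_idx, 0], mask.coords[hyper_idx, 1]
        field[hr, hc] = rng.normal(texture.hyper_mean, texture.speckle_sd, len(hyper_idx))

    pixels = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    record = ImageRecord(
        pixels=pixels, spacing_mm=spacing_mm, view=view, group_label=condition
    )
    return record, spec


def _image_seed(root_seed: int, subject_id: str, view: str) -> np.random.Generator:
    """Independent, reproducible per-image stream derived from one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(root_seed), zlib.crc32(subject_id.encode()), ("transverse", "longitudinal").index(view)]
        )
    )


def _draw_criteria(condition: str, sex: str, equivocal: bool, rng) -> dict:
    """Sheath/fluid/Doppler fields that reproduce the intended label.

    Fields straddle the diagnostic thresholds per group; for an
    equivocal subject the fields are flipped so the rule-based label
    contradicts the group label.
    """
    thr = SWELLING_THRESHOLDS_MM[sex]
    as_pos = (condition == "pos") != equivocal
    if as_pos:
        t_sheath = thr["transverse"] + abs(rng.normal(1.0, 0.6))
        l_sheath = thr["longitudinal"] + abs(rng.normal(0.5, 0.3))
        has_fluid = rng.random() < 0.5
        fluid = FLUID_DEPTH_THRESHOLD_MM + abs(rng.normal(0.8, 0.5)) if has_fluid else rng.uniform(0.0, 2.0)
        return {
            "t_sheath_mm": round(t_sheath, 2),
            "l_sheath_mm": round(l_sheath, 2),
            "fluid_mm": round(fluid, 2),
            "fluid_displaceable": has_fluid,
            "fluid_compressible": has_fluid,
            "color_flow": True,
        }
    # Negative presentation: sub-threshold structure; color flow may be
    # present without swelling and still yields a negative label.
    t_sheath = max(0.5, thr["transverse"] - abs(rng.normal(1.2, 0.6)))
    l_sheath = max(0.3, thr["longitudinal"] - abs(rng.normal(0.7, 0.35)))
    return {
        "t_sheath_mm": round(t_sheath, 2),
        "l_sheath_mm": round(l_sheath, 2),
        "fluid_mm": round(rng.uniform(0.0, 2.0), 2),
        "fluid_displaceable": bool(rng.random() < 0.3),
        "fluid_compressible": bool(rng.random() < 0.3),
        "color_flow": bool(rng.random() < 0.2),
    }


def simulate_study(
    cohort: CohortParams,
    out_dir,
    texture: Optional[dict] = None,
    spacing_mm: tuple[float, float] = (0.02, 0.02),
    size_px: tuple[int, int] = (128, 128),
    seed: Optional[int] = None,
) -> dict:
    """Generate a full synthetic study: images, sidecars, subject CSV, manifest.

    One image per subject and view (2 per subject), a ``subjects.csv``
    with demographics, criteria fields (matching the group label for
    ~95% of subjects) and reference labels, and a ``manifest.json``
    recording every parameter and file.  Deterministic given the seed.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    root_seed = int(cohort.seed if seed is None else seed)
    textures = {
        "transverse": default_texture("transverse"),
        "longitudinal": default_texture("longitudinal"),
    }
    if texture:
        textures.update(texture)

    scores = simulate_scores(
        CohortParams(
            transverse_pos=cohort.transverse_pos,
            transverse_neg=cohort.transverse_neg,
            longitudinal_pos=cohort.longitudinal_pos,
            longitudinal_neg=cohort.longitudinal_neg,
            n_pos=cohort.n_pos,
            n_neg=cohort.n_neg,
            seed=root_seed,
        )
    )
    meta_rng = np.random.default_rng(np.random.SeedSequence([root_seed, 0xC0F0]))

    files: list[str] = []
    rows: list[dict] = []
    for rec in scores.itertuples(index=False):
        condition = rec.group_label
        sex = "M" if meta_rng.random() < GROUP_MALE_FRACTION[condition] else "F"
        demo = GROUP_DEMOGRAPHICS[condition]
        equivocal = bool(meta_rng.random() < EQUIVOCAL_FRACTION)
        row = {
            "subject_id": rec.subject_id,
            "age": round(float(_truncated_normal(meta_rng, *demo["age"], 1, lo=18, hi=100)[0]), 1),
            "sex": sex,
            "weight_kg": round(float(_truncated_normal(meta_rng, *demo["weight_kg"], 1, lo=30, hi=150)[0]), 1),
            "height_cm": round(float(_truncated_normal(meta_rng, *demo["height_cm"], 1, lo=130, hi=200)[0]), 1),
            "duration_wk": round(float(_truncated_normal(meta_rng, *demo["duration_wk"], 1, lo=0.1, hi=200)[0]), 1),
            "tear_or_rupture": False,
            "prior_injection": False,
            "fracture_or_surgery": False,
            "reference_label": condition,
        }
        row.update(_draw_criteria(condition, sex, equivocal, meta_rng))

        for view, drawn_sd in (("transverse", rec.t_sd), ("longitudinal", rec.l_sd)):
            target_mean = GROUP_MEAN_TARGETS[view][condition]
            # Anchor the baseline speckle at the group's mean target so
            # the mixture's net mean shift is ~0: any drawn StdDev at
            # or above the speckle floor is then feasible.
            tex = replace(textures[view], baseline_mean=target_mean)
            _, _, sd_used = _match_with_clamp(target_mean, float(drawn_sd), tex, view)
            image, _ = simulate_tendon_image(
                view,
                condition,
                (target_mean, sd_used),
                texture=tex,
                spacing_mm=spacing_mm,
                size_px=size_px,
                seed=_image_seed(root_seed, rec.subject_id, view),
            )
            image.subject_id = rec.subject_id
            image.sex = sex
            path = img_dir / f"{rec.subject_id}_{view}.png"
            write_image(image, path)
            files.append(str(path.relative_to(out_dir)))
            files.append(str(path.with_suffix(".json").relative_to(out_dir)))
            row[f"{view[0]}_sd_target"] = round(sd_used, 4)
        rows.append(row)

    csv_path = out_dir / "subjects.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    files.append("subjects.csv")

    manifest = {
        "seed": root_seed,
        "n_pos": cohort.n_pos,
        "n_neg": cohort.n_neg,
        "spacing_mm": list(spacing_mm),
        "size_px": list(size_px),
        "cohort": asdict(cohort),
        "texture": {v: asdict(t) for v, t in textures.items()},
        "equivocal_fraction": EQUIVOCAL_FRACTION,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
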