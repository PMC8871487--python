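"""Synthetic lesion phantoms, perturbed segmentation outlines, and survival times.

This module emulates the inputs of a segmentation-reliability study: each
"patient" contributes one tumour-like lesion rendered on a 2D image, one or
more "manual" reference masks, and a set of stochastically perturbed
"automatic" masks standing in for the plausible segmentation variants a
probabilistic segmentation model would sample.  Right-censored survival times
are drawn from an exponential proportional-hazards model driven by a chosen
subset of image features, so that downstream survival models have a known
ground truth to recover.

The perturbation mechanism thresholds the signed distance transform of the
source mask at a spatially correlated Gaussian noise field.  With gradient
modulation enabled, the noise is locally amplified where the image gradient
across the boundary is weak, reproducing the qualitative behaviour of human
raters (and of generative segmentation networks): fuzzier boundaries receive
more variable outlines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


class SizingError(ValueError):
    """Lesion geometry does not fit inside the requested image."""


class PerturbationError(RuntimeError):
    """A variant mask could not be generated within the retry budget."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion.

    Lengths are in mm, intensities in arbitrary units.  ``axes_mm`` are the
    ellipse *semi*-axes; ``irregularity`` modulates the radius with a smooth
    random periodic function (0 = exact ellipse).  ``boundary_sharpness_mm``
    is the Gaussian edge-blur sigma; a pair ``(left, right)`` blurs the two
    image halves differently (used to study gradient-modulated perturbation).
    """

    image_size: int = 64
    pixel_spacing: float = 1.0
    axes_mm: tuple[float, float] = (10.0, 8.0)
    irregularity: float = 0.0
    texture_mean: float = 50.0
    texture_sd: float = 12.0
    texture_corr_mm: float = 3.0
    boundary_sharpness_mm: float | tuple[float, float] = 1.0
    background_mean: float = -40.0
    background_sd: float = 10.0
    modality: str = "CT-like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if min(self.axes_mm) <= 0:
            raise ValueError("ellipse axes must be positive")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.texture_corr_mm < 0:
            raise ValueError("texture correlation length must be >= 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters of the stochastic outline perturbation.

    ``amplitude_mm`` scales the boundary displacement field (0 reproduces the
    source mask exactly); ``noise_corr_mm`` is the smoothness length of the
    displacement field; ``gradient_modulation`` amplifies displacement where
    the local image gradient is weak.
    """

    n_variants: int = 100
    amplitude_mm: float = 1.5
    noise_corr_mm: float = 5.0
    gradient_modulation: bool = True
    min_dice: float = 0.6
    max_retries: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.min_dice < 1:
            raise ValueError("min_dice must lie in [0, 1)")


@dataclass(frozen=True)
class SurvivalGenSpec:
    """Exponential proportional-hazards generator for survival times.

    ``beta`` maps feature names to log hazard ratios applied to the
    z-standardized feature values; ``baseline_rate`` and ``censor_rate`` are
    events per year; ``admin_censor_time`` truncates follow-up.
    """

    beta: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 0.25
    censor_rate: float = 0.05
    admin_censor_time: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")


@dataclass
class LesionCase:
    """One lesion: image, ground-truth mask, manual mask(s), variant masks."""

    lesion_id: str
    patient_id: str
    modality: str
    image: np.ndarray
    spacing: float
    truth_mask: np.ndarray
    manual_masks: list[np.ndarray] = field(default_factory=list)
    variant_masks: list[np.ndarray] = field(default_factory=list)
    truth: PhantomSpec | None = None

    def __post_init__(self) -> None:
        for m in [self.truth_mask, *self.manual_masks, *self.variant_masks]:
            if m.shape != self.image.shape:
                raise ValueError("all masks must share the image grid")
            if not m.any():
                raise ValueError("masks must be nonempty")


@dataclass
class Cohort:
    """A bundle of lesion cases plus per-patient survival records."""

    cases: list[LesionCase]
    survival: pd.DataFrame  # columns: patient_id, time_years, event
    true_features: pd.DataFrame  # per-patient noiseless features (index patient_id)
    master_seed: int


# --------------------------------------------------------------------------
# Random-field helpers
# --------------------------------------------------------------------------

def _correlated_field(shape: tuple[int, int], corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with correlation length corr_px."""
    white = rng.standard_normal(shape)
    if corr_px <= 0:
        return white
    f = ndimage.gaussian_filter(white, corr_px, mode="reflect")
    sd = f.std()
    if sd < 1e-12:  # pathological: huge smoothing on tiny grid
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _single_component(mask: np.ndarray, connectivity: int = 1) -> bool:
    structure = ndimage.generate_binary_structure(2, connectivity)
    _, n = ndimage.label(mask, structure=structure)
    return n == 1


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


# --------------------------------------------------------------------------
# Phantom generation
# --------------------------------------------------------------------------

def _radial_modulation(theta: np.ndarray, rng: np.random.Generator, n_harmonics: int = 5) -> np.ndarray:
    """Smooth periodic unit-SD modulation g(theta) built from low harmonics."""
    g = np.zeros_like(theta)
    for m in range(2, 2 + n_harmonics):
        a, b = rng.standard_normal(2) / m
        g += a * np.cos(m * theta) + b * np.sin(m * theta)
    sd = g.std()
    return g / sd if sd > 0 else g


def make_phantom(spec: PhantomSpec, lesion_id: str = "lesion-000",
                 patient_id: str = "patient-000") -> LesionCase:
    """Render one lesion phantom: textured interior, blurred boundary, truth mask.

    The mask is defined purely by the (seeded) lesion geometry and contains no
    intensity noise; the interior texture is a correlated Gaussian random
    field with the requested mean/SD.  Raises :class:`SizingError` when the
    lesion cannot fit inside the image with a 2-pixel margin.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    sp = spec.pixel_spacing
    half = n * sp / 2.0

    shape_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    a, b = spec.axes_mm
    max_radius = max(a, b) * (1.0 + 3.5 * spec.irregularity)
    if max_radius + 2 * sp > half:
        raise SizingError(
            f"lesion radius {max_radius:.1f} mm does not fit in image of "
            f"half-extent {half:.1f} mm"
        )

    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    y = (yy - cy) * sp
    x = (xx - cx) * sp
    theta = np.arctan2(y, x)
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    if spec.irregularity > 0:
        g = _radial_modulation(theta, shape_rng)
        boundary = 1.0 + spec.irregularity * g
    else:
        boundary = np.ones_like(rho)
    mask = rho <= boundary
    mask = ndimage.binary_fill_holes(_largest_component(mask))
    if not mask.any():
        raise SizingError("degenerate lesion: empty mask")
    if not _single_component(mask, connectivity=1):
        # star-shaped construction makes this unreachable in practice
        raise SizingError("lesion mask is not 4-connected")

    # Interior / background textures: correlated random fields.
    corr_px = spec.texture_corr_mm / sp
    lesion_tex = spec.texture_mean + spec.texture_sd * _correlated_field((n, n), corr_px, rng)
    bg_tex = spec.background_mean + spec.background_sd * rng.standard_normal((n, n))

    # Boundary sharpness: blend via a blurred mask (per-half sigmas allowed).
    sharp = spec.boundary_sharpness_mm
    if np.isscalar(sharp):
        alpha = ndimage.gaussian_filter(mask.astype(float), max(float(sharp), 1e-6) / sp)
    else:
        s_left, s_right = sharp
        a_left = ndimage.gaussian_filter(mask.astype(float), max(float(s_left), 1e-6) / sp)
        a_right = ndimage.gaussian_filter(mask.astype(float), max(float(s_right), 1e-6) / sp)
        w = np.clip((xx - cx) / 4.0 + 0.5, 0.0, 1.0)  # smooth left->right switch
        alpha = (1 - w) * a_left + w * a_right
    image = alpha * lesion_tex + (1 - alpha) * bg_tex

    return LesionCase(
        lesion_id=lesion_id,
        patient_id=patient_id,
        modality=spec.modality,
        image=image,
        spacing=sp,
        truth_mask=mask,
        manual_masks=[mask.copy()],
        truth=spec,
    )


# --------------------------------------------------------------------------
# Mask perturbation
# --------------------------------------------------------------------------

def signed_distance_mm(mask: np.ndarray, spacing: float) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary (positive inside), mm."""
    mask = np.asarray(mask, bool)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def _gradient_weight(image: np.ndarray, mask: np.ndarray, spacing: float) -> np.ndarray:
    """Displacement weight inversely related to the boundary-gradient magnitude.

    The image gradient is evaluated on the source outline only and each
    outline pixel's weight is propagated along the boundary normal (nearest-
    outline lookup), so the whole displacement corridor of a boundary segment
    shares that segment's weight.  Normalized so the median outline weight is
    ~1; clipped to [0.2, 3] to keep variants well behaved.
    """
    smoothed = ndimage.gaussian_filter(image, 1.0)
    gy, gx = np.gradient(smoothed, spacing)
    grad = np.hypot(gx, gy)
    boundary = mask ^ ndimage.binary_erosion(mask)
    if not boundary.any():
        return np.ones_like(grad)
    ref = max(np.median(grad[boundary]), 1e-9)
    w_boundary = np.clip(2.0 / (1.0 + grad / ref), 0.2, 3.0)
    _, (iy, ix) = ndimage.distance_transform_edt(~boundary, return_indices=True)
    return w_boundary[iy, ix]


def sample_variant(mask: np.ndarray, spacing: float, pspec: PerturbationSpec,
                   rng: np.random.Generator, weight: np.ndarray | None = None) -> np.ndarray:
    """Draw one perturbed outline of ``mask``.

    Thresholds the signed distance transform at a correlated noise field;
    keeps the largest connected component and fills holes.  Resamples when
    the result is empty or overlaps the source by less than ``min_dice``.
    """
    if pspec.amplitude_mm == 0:
        return mask.copy()
    d = signed_distance_mm(mask, spacing)
    corr_px = pspec.noise_corr_mm / spacing
    for _ in range(pspec.max_retries):
        noise = _correlated_field(mask.shape, corr_px, rng)
        displacement = pspec.amplitude_mm * noise
        if weight is not None:
            displacement = displacement * weight
        variant = d > displacement
        variant = ndimage.binary_fill_holes(_largest_component(variant))
        if variant.any() and dice(variant, mask) >= pspec.min_dice:
            return variant
    raise PerturbationError(
        f"could not draw a variant with Dice >= {pspec.min_dice} in "
        f"{pspec.max_retries} attempts (amplitude {pspec.amplitude_mm} mm)"
    )


def perturb_mask(case: LesionCase, pspec: PerturbationSpec,
                 source_mask: np.ndarray | None = None) -> LesionCase:
    """Fill ``case.variant_masks`` with ``n_variants`` perturbed outlines.

    Perturbs the first manual mask (or ``source_mask`` if given).  With
    ``amplitude_mm == 0`` every variant equals the source exactly.
    """
    if not case.manual_masks:
        raise ValueError("case has no manual mask to perturb")
    source = case.manual_masks[0] if source_mask is None else source_mask
    rng = np.random.default_rng(pspec.seed)
    weight = (
        _gradient_weight(case.image, source, case.spacing)
        if pspec.gradient_modulation else None
    )
    variants = [
        sample_variant(source, case.spacing, pspec, rng, weight)
        for _ in range(pspec.n_variants)
    ]
    case.variant_masks = variants
    return case


# --------------------------------------------------------------------------
# Survival generation
# --------------------------------------------------------------------------

def simulate_survival(features: pd.DataFrame, sspec: SurvivalGenSpec) -> pd.DataFrame:
    """Draw right-censored survival records from an exponential PH model.

    ``features`` is a wide per-patient table (index = patient_id).  The linear
    predictor is x_std @ beta on internally z-standardized features; event
    times are exponential with rate ``baseline_rate * exp(lp)``; censoring is
    the minimum of an independent exponential and administrative truncation.
    """
    missing = [f for f in sspec.beta if f not in features.columns]
    if missing:
        raise KeyError(f"beta names missing from feature table: {missing}")
    rng = np.random.default_rng(sspec.seed)
    n = len(features)
    lp = np.zeros(n)
    for name, b in sspec.beta.items():
        col = features[name].to_numpy(float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        lp += b * z
    rate = sspec.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if sspec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / sspec.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, sspec.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {"patient_id": features.index, "time_years": time, "event": event}
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

_CT_DEFAULTS = dict(texture_mean_range=(20.0, 80.0), texture_sd_range=(8.0, 16.0),
                    background_mean=-40.0, background_sd=10.0)
_MRI_DEFAULTS = dict(texture_mean_range=(0.45, 0.75), texture_sd_range=(0.05, 0.11),
                     background_mean=0.15, background_sd=0.05)


@dataclass(frozen=True)
class CohortSpec:
    """Population-level distribution the per-lesion phantoms are drawn from.

    Lesion geometry varies widely between patients (driving between-subject
    feature variance) while the texture distribution is common to the cohort,
    so that shape/intensity summaries are reliable across outline variants and
    fine texture statistics are not — mirroring the reliability spectrum
    observed with real inter-rater segmentation variability.
    """

    n_patients: int = 50
    modality: str = "CT-like"
    image_size: int = 64
    pixel_spacing: float = 1.0
    semi_axis_range_mm: tuple[float, float] = (4.0, 14.0)
    irregularity_range: tuple[float, float] = (0.05, 0.25)
    texture_corr_range_mm: tuple[float, float] = (2.0, 5.0)
    sharpness_range_mm: tuple[float, float] = (0.5, 3.0)
    k_manual: int = 1
    manual_amplitude_mm: float = 0.5
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    survival: SurvivalGenSpec = field(default_factory=lambda: SurvivalGenSpec(
        beta={
            "original.firstorder.Mean": 0.8,
            "original.shape2D.PixelSurface": 0.6,
            "original.shape2D.MajorAxisLength": 0.4,
        }
    ))

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.k_manual < 1:
            raise ValueError("k_manual must be >= 1")


def _true_features(case: LesionCase) -> dict[str, float]:
    """Noiseless per-patient features from the ground-truth mask and image."""
    from .features import shape2d  # local import to avoid a cycle at import time

    vals = {}
    shape_vals = shape2d(case.truth_mask, case.spacing)
    for k, v in shape_vals.items():
        vals[f"original.shape2D.{k}"] = v
    vals["original.firstorder.Mean"] = float(case.image[case.truth_mask].mean())
    return vals


def make_cohort(spec: CohortSpec, master_seed: int = 0) -> Cohort:
    """Generate a reproducible cohort: lesions, outlines, survival records."""
    ss = np.random.SeedSequence(master_seed)
    case_seeds = ss.spawn(spec.n_patients)
    defaults = _CT_DEFAULTS if spec.modality.startswith("CT") else _MRI_DEFAULTS

    cases: list[LesionCase] = []
    rows = {}
    for i, child in enumerate(case_seeds):
        rng = np.random.default_rng(child)
        lo, hi = spec.semi_axis_range_mm
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        a, b = max(a, b), min(a, b)
        m_lo, m_hi = defaults["texture_mean_range"]
        pspec = PhantomSpec(
            image_size=spec.image_size,
            pixel_spacing=spec.pixel_spacing,
            axes_mm=(a, b),
            irregularity=rng.uniform(*spec.irregularity_range),
            texture_mean=rng.uniform(m_lo, m_hi),
            texture_sd=rng.uniform(*defaults["texture_sd_range"]),
            texture_corr_mm=rng.uniform(*spec.texture_corr_range_mm),
            boundary_sharpness_mm=rng.uniform(*spec.sharpness_range_mm),
            background_mean=defaults["background_mean"],
            background_sd=defaults["background_sd"],
            modality=spec.modality,
            seed=int(rng.integers(2**31)),
        )
        case = make_phantom(pspec, lesion_id=f"lesion-{i:03d}", patient_id=f"patient-{i:03d}")

        # Manual raters: k low-amplitude perturbations of the truth (the first
        # manual mask is the truth itself when manual_amplitude is 0).
        if spec.k_manual == 1 and spec.manual_amplitude_mm == 0:
            case.manual_masks = [case.truth_mask.copy()]
        else:
            man_spec = replace(
                spec.perturbation,
                n_variants=spec.k_manual,
                amplitude_mm=spec.manual_amplitude_mm,
                seed=int(rng.integers(2**31)),
            )
            man_rng = np.random.default_rng(man_spec.seed)
            weight = (
                _gradient_weight(case.image, case.truth_mask, case.spacing)
                if man_spec.gradient_modulation else None
            )
            case.manual_masks = [
                sample_variant(case.truth_mask, case.spacing, man_spec, man_rng, weight)
                for _ in range(spec.k_manual)
            ]

        var_spec = replace(spec.perturbation, seed=int(rng.integers(2**31)))
        perturb_mask(case, var_spec, source_mask=case.truth_mask)
        cases.append(case)
        rows[case.patient_id] = _true_features(case)

    true_feats = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    surv_spec = replace(spec.survival, seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31)))
    survival = simulate_survival(true_feats, surv_spec)
    return Cohort(cases=cases, survival=survival, true_features=true_feats,
                  master_seed=master_seed)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: NIfTI images/masks + JSON sidecars + CSVs."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for case in cohort.cases:
        d = outdir / case.lesion_id
        d.mkdir(exist_ok=True)
        affine = np.diag([case.spacing, case.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(case.image.astype(np.float32), affine), d / "image.nii.gz")
        masks = np.stack([case.truth_mask, *case.manual_masks, *case.variant_masks])
        nib.save(nib.Nifti1Image(masks.astype(np.uint8), affine), d / "masks.nii.gz")
        meta = {
            "lesion_id": case.lesion_id,
            "patient_id": case.patient_id,
            "modality": case.modality,
            "spacing": case.spacing,
            "n_manual": len(case.manual_masks),
            "n_variants": len(case.variant_masks),
            "truth": asdict(case.truth) if case.truth else None,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))
    cohort.survival.to_csv(outdir / "survival.csv", index=False)
    cohort.true_features.to_csv(outdir / "true_features.csv")
    (outdir / "cohort.json").write_text(json.dumps(
        {"master_seed": cohort.master_seed, "n_patients": len(cohort.cases)}, indent=2))
    return outdir


def load_cohort(indir: str | Path) -> Cohort:
    """Read a cohort written by :func:`save_cohort`."""
    import nibabel as nib

    indir = Path(indir)
    info = json.loads((indir / "cohort.json").read_text())
    cases = []
    for d in sorted(p for p in indir.iterdir() if p.is_dir()):
        meta = json.loads((d / "meta.json").read_text())
        image = np.asarray(nib.load(d / "image.nii.gz").dataobj, dtype=float)
        masks = np.asarray(nib.load(d / "masks.nii.gz").dataobj, dtype=bool)
        k, v = meta["n_manual"], meta["n_variants"]
        cases.append(LesionCase(
            lesion_id=meta["lesion_id"],
            patient_id=meta["patient_id"],
            modality=meta["modality"],
            image=image,
            spacing=meta["spacing"],
            truth_mask=masks[0],
            manual_masks=[m for m in masks[1:1 + k]],
            variant_masks=[m for m in masks[1 + k:1 + k + v]],
            truth=PhantomSpec(**{**meta["truth"],
                                 "axes_mm": tuple(meta["truth"]["axes_mm"]),
                                 "boundary_sharpness_mm": _sharp_from_json(
                                     meta["truth"]["boundary_sharpness_mm"])})
            if meta["truth"] else None,
        ))
    survival = pd.read_csv(indir / "survival.csv")
    true_features = pd.read_csv(indir / "true_features.csv", index_col=0)
    return Cohort(cases=cases, survival=survival, true_features=true_features,
                  master_seed=info["master_seed"])


def _sharp_from_json(v):
    return tuple(v) if isinstance(v, list) else v
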