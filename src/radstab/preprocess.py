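"""Cropping, exclusion and slice-selection rules producing the 2D analysis frame.

A lesion enters the feature pipeline as a square crop centred on the mask
centroid.  Lesions are excluded when they are too small (volume below a
threshold), too large (mask not fully contained in the box), or when the
crop slice contains multiple disjoint lesions; the three rules are applied in
that order and the first violation determines the status.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

KEPT = "kept"
TOO_SMALL = "too_small"
EXCEEDS_BOX = "exceeds_box"
MULTIPLE_LESIONS = "multiple_lesions"


@dataclass(frozen=True)
class CropRule:
    """Square crop geometry and exclusion thresholds.

    ``min_volume_mm3`` applies to area x slice thickness for 2D inputs
    (``slice_thickness_mm`` defaults to 1).  ``pad_value`` fills the crop when
    the box extends past the image border.
    """

    box_size: int = 128
    min_volume_mm3: float = 30.0
    slice_thickness_mm: float = 1.0
    pad_value: float | None = None  # None -> image minimum

    def __post_init__(self) -> None:
        if self.box_size <= 0:
            raise ValueError("box_size must be positive")
        if self.min_volume_mm3 < 0:
            raise ValueError("min_volume_mm3 must be >= 0")


@dataclass
class AnalysisFrame:
    """One cropped 2D frame: image patch, mask patch, provenance, status."""

    lesion_id: str
    image: np.ndarray
    mask: np.ndarray
    spacing: float
    offset: tuple[int, int]  # (row, col) of crop origin in the source image
    status: str = KEPT


@dataclass
class CroppedCase:
    """All segmentations of one lesion cropped with a shared offset."""

    lesion_id: str
    patient_id: str
    modality: str
    image: np.ndarray
    spacing: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    offset: tuple[int, int] = (0, 0)
    status: str = KEPT


def size_boxes(max_diameters_mm, spacing_mm: float = 1.0) -> int:
    """Smallest even box (pixels) covering mean + 2 SD of the max diameters."""
    d = np.asarray(list(max_diameters_mm), float)
    if d.size < 2:
        raise ValueError("need at least two lesion diameters to size the box")
    need_mm = d.mean() + 2.0 * d.std()
    px = math.ceil(need_mm / spacing_mm)
    return px + (px % 2)


def _crop_bounds(center: tuple[float, float], box: int,
                 shape: tuple[int, int]) -> tuple[int, int, int, int]:
    r0 = int(round(center[0])) - box // 2
    c0 = int(round(center[1])) - box // 2
    return r0, c0, r0 + box, c0 + box


def _extract_patch(arr: np.ndarray, bounds, pad_value: float) -> np.ndarray:
    r0, c0, r1, c1 = bounds
    h, w = arr.shape
    patch = np.full((r1 - r0, c1 - c0), pad_value, dtype=arr.dtype)
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, h), min(c1, w)
    if sr0 < sr1 and sc0 < sc1:
        patch[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = arr[sr0:sr1, sc0:sc1]
    return patch


def crop_and_filter(image: np.ndarray, mask: np.ndarray, spacing: float,
                    rule: CropRule, lesion_id: str = "lesion") -> AnalysisFrame:
    """Crop one (image, mask) pair and apply the exclusion rules in order.

    The box is centred on the mask centroid (rounded to the nearest pixel);
    if it extends past the image border the patch is padded with a
    background-level constant and the event logged.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    volume = mask.sum() * spacing**2 * rule.slice_thickness_mm

    cy, cx = ndimage.center_of_mass(mask)
    bounds = _crop_bounds((cy, cx), rule.box_size, mask.shape)
    pad = rule.pad_value if rule.pad_value is not None else float(np.min(image))
    if bounds[0] < 0 or bounds[1] < 0 or bounds[2] > mask.shape[0] or bounds[3] > mask.shape[1]:
        log.info("lesion %s: crop box extends past the image border; padding with %.3g",
                 lesion_id, pad)
    patch_img = _extract_patch(np.asarray(image, float), bounds, pad)
    patch_mask = _extract_patch(mask, bounds, False)

    if volume < rule.min_volume_mm3:
        status = TOO_SMALL
    elif patch_mask.sum() < mask.sum():
        status = EXCEEDS_BOX
    else:
        _, n_comp = ndimage.label(patch_mask)
        status = MULTIPLE_LESIONS if n_comp > 1 else KEPT

    return AnalysisFrame(lesion_id=lesion_id, image=patch_img, mask=patch_mask,
                         spacing=spacing, offset=(bounds[0], bounds[1]), status=status)


def crop_case(case, rule: CropRule) -> CroppedCase:
    """Crop every segmentation of a lesion with one shared, centroid-based box.

    The reference (first manual) mask determines the offset and the exclusion
    status; variant masks that would poke out of the shared box keep only
    their in-box part (they share the reference's status decision).
    """
    ref = case.manual_masks[0]
    frame = crop_and_filter(case.image, ref, case.spacing, rule, case.lesion_id)
    masks: dict[str, np.ndarray] = {}
    bounds = (frame.offset[0], frame.offset[1],
              frame.offset[0] + rule.box_size, frame.offset[1] + rule.box_size)
    # truncating a non-reference mask at the box edge can split it; keep the
    # largest piece so every cropped mask stays a single component
    def _crop_mask(m):
        patch = _extract_patch(np.asarray(m, bool), bounds, False)
        labels, n = ndimage.label(patch)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            patch = labels == (1 + int(np.argmax(sizes)))
        return patch

    for i, m in enumerate(case.manual_masks):
        masks[f"manual-{i:02d}"] = _crop_mask(m)
    for i, m in enumerate(case.variant_masks):
        masks[f"auto-{i:03d}"] = _crop_mask(m)
    return CroppedCase(lesion_id=case.lesion_id, patient_id=case.patient_id,
                       modality=case.modality, image=frame.image, spacing=case.spacing,
                       masks=masks, offset=frame.offset, status=frame.status)


def crop_cohort(cases, rule: CropRule) -> tuple[list[CroppedCase], pd.DataFrame]:
    """Crop a cohort; returns kept cases plus the full exclusion log."""
    kept, records = [], []
    for case in cases:
        cc = crop_case(case, rule)
        records.append({"lesion_id": cc.lesion_id, "status": cc.status})
        if cc.status == KEPT:
            kept.append(cc)
    return kept, pd.DataFrame.from_records(records)


def write_exclusion_log(logdf: pd.DataFrame, path: str | Path) -> None:
    logdf.to_csv(path, index=False)


def select_axial_slice(mask3d: np.ndarray) -> int:
    """Index of the axial slice with the greatest mask area (ties -> lower index).

    3D masks are indexed (slice, row, col); 2D masks pass through as slice 0.
    """
    mask3d = np.asarray(mask3d, bool)
    if not mask3d.any():
        raise ValueError("mask is empty")
    if mask3d.ndim == 2:
        return 0
    areas = mask3d.reshape(mask3d.shape[0], -1).sum(axis=1)
    return int(np.argmax(areas))  # argmax returns the first maximum
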