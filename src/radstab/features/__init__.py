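"""Radiomic feature computation for 2D analysis frames.

Families: first-order histogram statistics, 2D shape descriptors, and the
four gray-level texture matrices (co-occurrence, run-length, size-zone,
dependence), each optionally recomputed on the four sub-bands of a
single-level stationary wavelet transform.  Feature names are namespaced as
``<filter>.<family>.<name>`` with filter in {original, wavelet-LL, wavelet-LH,
wavelet-HL, wavelet-HH}; shape features exist only under ``original``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._firstorder import firstorder
from ._shape import shape2d
from ._matrices import (
    glcm_matrix, glcm_features,
    glrlm_matrix, glrlm_features,
    glszm_matrix, glszm_features,
    gldm_matrix, gldm_features,
)
from ._wavelet import wavelet_variants, BAND_NAMES
from .extract import FeatureConfig, extract_frame, extract_all, wide_to_long, long_to_wide

__all__ = [
    "DiscretizationRule", "FeatureConfig",
    "discretize", "discretize_values",
    "firstorder", "shape2d",
    "glcm_matrix", "glcm_features",
    "glrlm_matrix", "glrlm_features",
    "glszm_matrix", "glszm_features",
    "gldm_matrix", "gldm_features",
    "wavelet_variants", "BAND_NAMES",
    "extract_frame", "extract_all", "wide_to_long", "long_to_wide",
]


@dataclass(frozen=True)
class DiscretizationRule:
    """How in-mask intensities are mapped to integer gray levels 1..Ng.

    ``fixed_bin_count`` spans [min, max] of the in-mask intensities with
    ``n_bins`` equal-width bins (the default, appropriate for arbitrary
    intensity scales); ``fixed_bin_width`` uses bins of ``bin_width`` anchored
    at the in-mask minimum.
    """

    mode: str = "fixed_bin_count"
    n_bins: int = 32
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == "fixed_bin_width" and not (self.bin_width and self.bin_width > 0):
            raise ValueError("bin_width must be positive")


def discretize_values(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of a 1D value array to integer levels 1..n_bins."""
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.shape, int)
    lv = np.floor((x - lo) / (hi - lo) * n_bins).astype(int) + 1
    return np.clip(lv, 1, n_bins)


def discretize(image: np.ndarray, mask: np.ndarray,
               rule: DiscretizationRule = DiscretizationRule()) -> tuple[np.ndarray, int]:
    """Gray-level image restricted to the mask.

    Returns ``(levels, n_levels)`` where ``levels`` holds integers 1..n_levels
    inside the mask and 0 outside.  A constant region maps to level 1.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(image, float)[mask]
    levels = np.zeros(image.shape, int)
    if rule.mode == "fixed_bin_count":
        levels[mask] = discretize_values(x, rule.n_bins)
        n_levels = rule.n_bins
    else:
        lv = np.floor((x - x.min()) / rule.bin_width).astype(int) + 1
        levels[mask] = lv
        n_levels = int(lv.max())
    return levels, n_levels
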