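"""Cohort-level feature extraction: frames in, feature table out.

The canonical in-memory container is a *wide* pandas DataFrame indexed by
``(lesion_id, segmentation_id)`` with one column per namespaced feature;
:func:`wide_to_long` / :func:`long_to_wide` convert to the long CSV layout
``(lesion_id, segmentation_id, feature_name, value)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

INTENSITY_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm")


@dataclass(frozen=True)
class FeatureConfig:
    """Which families to compute and how to discretize.

    With ``wavelets`` enabled the intensity families are recomputed on each
    of the four stationary-wavelet sub-bands, multiplying the intensity
    feature count by five.
    """

    n_bins: int = 32
    discretization: str = "fixed_bin_count"
    bin_width: float | None = None
    families: tuple[str, ...] = ("shape2D",) + INTENSITY_FAMILIES
    wavelets: bool = False
    wavelet: str = "coif1"


def _intensity_features(image: np.ndarray, mask: np.ndarray,
                        config: FeatureConfig) -> dict[str, float]:
    from . import (DiscretizationRule, discretize, firstorder,
                   glcm_features, glrlm_features, glszm_features, gldm_features)

    rule = DiscretizationRule(mode=config.discretization, n_bins=config.n_bins,
                              bin_width=config.bin_width)
    levels, n_levels = discretize(image, mask, rule)
    out: dict[str, float] = {}
    if "firstorder" in config.families:
        for k, v in firstorder(image, mask, levels=levels, n_levels=n_levels).items():
            out[f"firstorder.{k}"] = v
    # matrices only see in-mask levels: restrict to the mask bounding box
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    lv, mk = levels[sl], mask[sl]
    for family, fn in (("glcm", glcm_features), ("glrlm", glrlm_features),
                       ("glszm", glszm_features), ("gldm", gldm_features)):
        if family in config.families:
            for k, v in fn(lv, mk, n_levels).items():
                out[f"{family}.{k}"] = v
    return out


def extract_frame(image: np.ndarray, mask: np.ndarray, spacing: float,
                  config: FeatureConfig = FeatureConfig(),
                  wavelet_bands: dict[str, np.ndarray] | None = None) -> dict[str, float]:
    """All features of one (image, mask) frame, namespaced by filter/family.

    ``wavelet_bands`` lets callers reuse the (mask-independent) wavelet
    transform of the image across many masks of the same lesion.
    """
    from . import shape2d, wavelet_variants

    out: dict[str, float] = {}
    if "shape2D" in config.families:
        for k, v in shape2d(mask, spacing).items():
            out[f"original.shape2D.{k}"] = v
    for k, v in _intensity_features(image, mask, config).items():
        out[f"original.{k}"] = v
    if config.wavelets:
        if wavelet_bands is None:
            try:
                wavelet_bands = wavelet_variants(image, config.wavelet)
            except ValueError as exc:
                log.warning("skipping wavelet families: %s", exc)
                wavelet_bands = {}
        for band, sub in wavelet_bands.items():
            for k, v in _intensity_features(sub, mask, config).items():
                out[f"wavelet-{band}.{k}"] = v
    return out


def extract_all(cropped_cases, config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature table for a cohort of cropped cases.

    Each case must expose ``lesion_id``, ``image``, ``spacing`` and ``masks``
    (an ordered mapping segmentation_id -> binary mask).  Columns containing
    any non-finite value are dropped run-wide and logged, so every row shares
    an identical, finite feature set.
    """
    from . import wavelet_variants

    rows = {}
    for case in cropped_cases:
        bands = None
        if config.wavelets:
            try:
                bands = wavelet_variants(case.image, config.wavelet)
            except ValueError as exc:
                log.warning("lesion %s: skipping wavelets (%s)", case.lesion_id, exc)
                bands = {}
        for seg_id, mask in case.masks.items():
            rows[(case.lesion_id, seg_id)] = extract_frame(
                case.image, mask, case.spacing, config, wavelet_bands=bands)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["lesion_id", "segmentation_id"])
    table = table.sort_index()
    bad = table.columns[~np.isfinite(table.to_numpy()).all(axis=0)]
    if len(bad):
        log.warning("dropping %d feature(s) with non-finite values: %s",
                    len(bad), list(bad))
        table = table.drop(columns=bad)
    return table


def wide_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Wide (lesion, segmentation) x feature table -> long rows."""
    long = table.stack().rename("value").reset_index()
    long.columns = ["lesion_id", "segmentation_id", "feature_name", "value"]
    return long


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`wide_to_long`."""
    if long.duplicated(["lesion_id", "segmentation_id", "feature_name"]).any():
        raise ValueError("duplicate (lesion, segmentation, feature) keys")
    return long.pivot(index=["lesion_id", "segmentation_id"],
                      columns="feature_name", values="value")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write long-format CSV plus a wide CSV and a column-dictionary JSON."""
    path = Path(path)
    wide_to_long(table).to_csv(path, index=False)
    table.to_csv(path.with_name(path.stem + "_wide.csv"))
    dictionary = {
        name: {"filter": name.split(".")[0], "family": name.split(".")[1],
               "feature": name.split(".")[2]}
        for name in table.columns
    }
    path.with_suffix(".json").write_text(json.dumps(dictionary, indent=2))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format CSV back into the wide in-memory layout."""
    return long_to_wide(pd.read_csv(path))
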