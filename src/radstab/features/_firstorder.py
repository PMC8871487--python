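"""First-order (histogram) intensity features.

Definitions follow the common standardized-radiomics conventions: variance is
the population (biased) variance, kurtosis is reported as *excess* kurtosis
(0 for a Gaussian), and uniformity/entropy are computed on the discretized
in-mask histogram.
"""

from __future__ import annotations

import numpy as np


def firstorder(image: np.ndarray, mask: np.ndarray, levels: np.ndarray | None = None,
               n_levels: int | None = None) -> dict[str, float]:
    """Histogram features of the in-mask intensities.

    ``levels`` (discretized gray levels, 1..n_levels) feeds uniformity and
    entropy; when omitted they are computed from a 32-bin histogram of the raw
    values.  Single-pixel masks get skewness/kurtosis 0 by convention.
    """
    x = np.asarray(image, float)[np.asarray(mask, bool)]
    if x.size == 0:
        raise ValueError("mask is empty")

    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = 0.0
        kurt = 0.0

    if levels is None:
        if n_levels is None:
            n_levels = 32
        from . import discretize_values
        lv = discretize_values(x, n_levels)
    else:
        lv = np.asarray(levels, int)[np.asarray(mask, bool)]
        if n_levels is None:
            n_levels = int(lv.max())
    counts = np.bincount(lv, minlength=n_levels + 1)[1:]
    p = counts / counts.sum()
    pz = p[p > 0]

    q10, q25, med, q75, q90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "Mean": mean,
        "Median": float(med),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Uniformity": float(np.sum(p**2)),
        "Entropy": float(-np.sum(pz * np.log2(pz))),
        "Energy": float(np.sum(x**2)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "InterquartileRange": float(q75 - q25),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Percentile10": float(q10),
        "Percentile90": float(q90),
    }
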