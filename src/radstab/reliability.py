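"""Inter-outline reliability of radiomic features via the one-way ICC.

ICC(1) treats the segmentation variants of a lesion as interchangeable
"raters" in a one-way random-effects ANOVA: with between-subject mean square
MSB (df n-1) and within-subject mean square MSW (df n(k-1)),

    ICC(1) = (MSB - MSW) / (MSB + (k - 1) * MSW),

which is the fraction of total variance attributable to true between-lesion
differences.  Features are ranked by ICC, grouped into quartiles, and
thresholded into the high (> 0.99) / low (< 0.75) / all signatures used by
the downstream survival models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGH_ICC_THRESHOLD = 0.99
LOW_ICC_THRESHOLD = 0.75


@dataclass
class SignatureSet:
    """Feature subsets by reliability: high (ICC > 0.99), low (< 0.75), all."""

    high: list[str] = field(default_factory=list)
    low: list[str] = field(default_factory=list)
    all: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ValueError("high and low signatures must be disjoint")

    def get(self, name: str) -> list[str]:
        return {"high": self.high, "low": self.low, "all": self.all}[name]


def icc1(matrix: np.ndarray) -> float:
    """One-way random-effects ICC of an n-subjects x k-raters matrix.

    Requires n >= 2 subjects and k >= 2 raters with no missing cells.  A
    fully constant matrix (MSB = MSW = 0) returns 1.0 by convention so that
    downstream signature logic stays total; use :func:`icc1_flagged` to
    detect that degeneracy.
    """
    value, _ = icc1_flagged(matrix)
    return value


def icc1_flagged(matrix: np.ndarray) -> tuple[float, bool]:
    """ICC(1) plus a flag marking the degenerate all-constant case."""
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings matrix must be at least 2 subjects x 2 raters")
    if not np.isfinite(m).all():
        raise ValueError("ratings matrix contains missing/non-finite cells")
    values = _icc1_stack(m[None])
    return float(values[0]), bool(np.ptp(m) == 0)


def _icc1_stack(arr: np.ndarray) -> np.ndarray:
    """Vectorized ICC(1) over a stack of matrices, shape (..., n, k)."""
    n, k = arr.shape[-2], arr.shape[-1]
    row_mean = arr.mean(axis=-1)
    grand = row_mean.mean(axis=-1, keepdims=True)
    msb = k * ((row_mean - grand) ** 2).sum(axis=-1) / (n - 1)
    msw = ((arr - row_mean[..., None]) ** 2).sum(axis=(-2, -1)) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msb - msw) / denom
    return np.where(denom == 0, 1.0, icc)  # all-constant matrix -> 1 by convention


def icc_table(feature_table: pd.DataFrame, rater_group: str = "auto",
              dataset: str = "synthetic", modality: str = "CT-like") -> pd.DataFrame:
    """Per-feature ICC(1) across segmentation variants, sorted descending.

    ``feature_table`` is the wide (lesion_id, segmentation_id)-indexed table;
    ``rater_group`` selects segmentation ids by prefix ("manual" or "auto").
    Lesions missing any rater of the group are dropped (complete design).
    Returns columns: feature_name, dataset, modality, icc, degenerate.
    """
    # index: (subject, segmentation) — accepts lesion- or patient-keyed tables
    seg_ids = feature_table.index.get_level_values(-1)
    sub = feature_table[seg_ids.str.startswith(rater_group)]
    if sub.empty:
        raise ValueError(f"no segmentations with prefix {rater_group!r}")
    counts = sub.groupby(level=0).size()
    k = int(counts.max())
    complete = counts[counts == k].index
    if len(complete) < len(counts):
        sub = sub[sub.index.get_level_values(0).isin(complete)]
    n = len(complete)
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 lesions and >= 2 raters (got n={n}, k={k})")

    arr = (sub.sort_index().to_numpy()
           .reshape(n, k, sub.shape[1]).transpose(2, 0, 1))  # features x n x k
    iccs = _icc1_stack(arr)
    degenerate = np.array([np.ptp(a) == 0 for a in arr])
    out = pd.DataFrame({
        "feature_name": sub.columns,
        "dataset": dataset,
        "modality": modality,
        "icc": iccs,
        "degenerate": degenerate,
    })
    return (out.sort_values(["icc", "feature_name"], ascending=[False, True])
            .reset_index(drop=True))


def quartile_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Add a quartile column: Q1 = most reliable 25% ... Q4 = least reliable.

    Group sizes are n//4 each, with the remainder distributed to the outer
    quartiles first (Q1, Q4, then Q2, Q3); ties in ICC are broken by feature
    name so the partition is deterministic.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 features to form quartiles")
    t = table.sort_values(["icc", "feature_name"], ascending=[False, True]).copy()
    n = len(t)
    sizes = {q: n // 4 for q in ("Q1", "Q2", "Q3", "Q4")}
    for q in ("Q1", "Q4", "Q2", "Q3")[:n % 4]:
        sizes[q] += 1
    labels = np.concatenate([np.full(sizes[q], q) for q in ("Q1", "Q2", "Q3", "Q4")])
    t["quartile"] = labels
    return t.reset_index(drop=True)


def threshold_signatures(table: pd.DataFrame) -> SignatureSet:
    """Strict-threshold signatures: high ICC > 0.99, low ICC < 0.75, all."""
    high = sorted(table.loc[table["icc"] > HIGH_ICC_THRESHOLD, "feature_name"])
    low = sorted(table.loc[table["icc"] < LOW_ICC_THRESHOLD, "feature_name"])
    import logging
    if not high or not low:
        logging.getLogger(__name__).warning(
            "empty signature group(s): high=%d low=%d features", len(high), len(low))
    return SignatureSet(high=high, low=low, all=sorted(table["feature_name"]))


def signature_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Append in_high/in_low membership columns to an ICC table."""
    t = table.copy()
    t["in_high"] = t["icc"] > HIGH_ICC_THRESHOLD
    t["in_low"] = t["icc"] < LOW_ICC_THRESHOLD
    return t


def compare_manual_auto(t_manual: pd.DataFrame, t_auto: pd.DataFrame) -> pd.DataFrame:
    """Per-quartile paired comparison of manual vs automatic ICCs.

    Quartiles are assigned from the *manual* table; within each quartile a
    Wilcoxon signed-rank test compares the two ICC sets paired by feature.
    Returns exactly four rows with the statistic, p-value, significance stars
    and an ``exact`` flag for quartiles smaller than five features.
    """
    from .stats import wilcoxon_signed_rank, significance_stars

    if set(t_manual["feature_name"]) != set(t_auto["feature_name"]):
        raise ValueError("manual and automatic tables must share the feature set")
    tq = quartile_groups(t_manual)
    auto_icc = t_auto.set_index("feature_name")["icc"]
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        feats = tq.loc[tq["quartile"] == q, "feature_name"]
        a = tq.set_index("feature_name").loc[feats, "icc"].to_numpy()
        b = auto_icc.loc[feats].to_numpy()
        res = wilcoxon_signed_rank(a, b)
        rows.append({
            "quartile": q,
            "n_features": len(feats),
            "median_manual": float(np.median(a)),
            "median_auto": float(np.median(b)),
            "median_difference": float(np.median(a - b)),
            "statistic": res.statistic,
            "p_value": res.p_value,
            "stars": significance_stars(res.p_value),
            "exact": len(feats) < 5 or res.method == "exact",
        })
    return pd.DataFrame(rows)
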