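"""Statistical test battery for comparing C-index and ICC distributions.

Wraps the scipy implementations of Friedman's test, Wilcoxon's signed-rank
test, Bartlett's variance test and the D'Agostino-Pearson normality test
behind a uniform :class:`TestResult`, and composes them into the three-group
signature comparison: Friedman as the a-priori test across {high, all, low},
pairwise Wilcoxon on locations and Bartlett on spreads, with a Bonferroni
level of 0.05/2 (two pairwise comparisons per modality).  All tests are
two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05
BONFERRONI_COMPARISONS = 2


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    alpha_adjusted: float = DEFAULT_ALPHA
    degenerate: bool = False
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def significance_stars(p: float) -> str:
    """ns / * / ** / *** convention at 0.05, 0.01, 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def friedman(*groups, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Friedman rank test over k >= 3 matched groups (blocks = observations).

    Identical groups (all blocks fully tied) return statistic 0, p = 1 with a
    degeneracy flag instead of the 0/0 tie correction.
    """
    if len(groups) < 3:
        raise ValueError("Friedman's test needs at least 3 matched groups")
    arrs = [np.asarray(g, float) for g in groups]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all groups must have the same block count")
    if n < 2:
        raise ValueError("need at least 2 blocks")
    block = np.column_stack(arrs)
    if np.all(np.ptp(block, axis=1) == 0):
        return TestResult("friedman", 0.0, 1.0, n, alpha, degenerate=True)
    stat, p = sps.friedmanchisquare(*arrs)
    return TestResult("friedman", float(stat), float(p), n, alpha)


def wilcoxon_signed_rank(a, b=None, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for <= 25 nonzero untied differences and the
    normal approximation with continuity correction otherwise.  All-zero
    differences give p = 1 with a degeneracy flag.
    """
    a = np.asarray(a, float)
    d = a - np.asarray(b, float) if b is not None else a
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult("wilcoxon", 0.0, 1.0, 0, alpha, degenerate=True)
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                      int(nz.size), alpha, method=method)


def bartlett(*groups, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Bartlett's test of equal variances across k >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least 2 groups")
    arrs = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    if any(a.var(ddof=1) == 0 for a in arrs):
        raise ValueError("zero-variance group: Bartlett statistic undefined")
    stat, p = sps.bartlett(*arrs)
    return TestResult("bartlett", float(stat), float(p),
                      int(sum(len(a) for a in arrs)), alpha)


def dagostino_normality(sample, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """D'Agostino-Pearson K^2 omnibus normality test (skewness + kurtosis).

    Requires n >= 20 for the underlying z-approximations; constant samples
    are rejected as errors (zero variance).
    """
    x = np.asarray(sample, float)
    if x.size < 20:
        raise ValueError("D'Agostino's test needs n >= 20")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = sps.normaltest(x)
    return TestResult("dagostino", float(stat), float(p), int(x.size), alpha)


@dataclass
class SignatureComparison:
    """Full three-group report: a-priori Friedman plus pairwise tests."""

    friedman: TestResult
    pairwise_location: dict[str, TestResult]
    pairwise_spread: dict[str, TestResult]
    normality: dict[str, TestResult | None]
    location_test_used: str
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"comparison": "high|all|low", "test": "friedman",
                 "statistic": self.friedman.statistic, "p_value": self.friedman.p_value,
                 "alpha_adjusted": self.friedman.alpha_adjusted,
                 "significant": self.friedman.significant,
                 "stars": significance_stars(self.friedman.p_value)}]
        for label, res in {**self.pairwise_location, **self.pairwise_spread}.items():
            rows.append({"comparison": label, "test": res.test,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "alpha_adjusted": res.alpha_adjusted,
                         "significant": res.significant,
                         "stars": significance_stars(res.p_value)})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Signature comparison"]
        for name in self.means:
            lines.append(f"  {name:5s}: C mean {self.means[name]:.3f}, SD {self.sds[name]:.3f}")
        f = self.friedman
        lines.append(f"  Friedman (a priori): chi2 = {f.statistic:.3f}, "
                     f"p = {f.p_value:.3g} [{significance_stars(f.p_value)}]")
        for label, res in self.pairwise_location.items():
            lines.append(f"  {self.location_test_used} {label}: p = {res.p_value:.3g} "
                         f"[{significance_stars(res.p_value)}] (alpha {res.alpha_adjusted})")
        for label, res in self.pairwise_spread.items():
            lines.append(f"  Bartlett {label}: p = {res.p_value:.3g} "
                         f"[{significance_stars(res.p_value)}] (alpha {res.alpha_adjusted})")
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def compare_signatures(distributions: dict[str, np.ndarray],
                       alpha: float = DEFAULT_ALPHA,
                       n_comparisons: int = BONFERRONI_COMPARISONS) -> SignatureComparison:
    """Compare the C-index distributions of the high / all / low signatures.

    ``distributions`` maps signature names to matched value arrays (same
    (fold, segmentation) order).  A D'Agostino pre-check on each distribution
    selects the paired location test: Wilcoxon when normality is rejected for
    any group (the expected case), a paired t-test otherwise.  Pairwise
    comparisons are high-vs-all and low-vs-all at alpha / n_comparisons.
    """
    warnings: list[str] = []
    present = {k: np.asarray(v, float) for k, v in distributions.items() if v is not None}
    for name in ("high", "all", "low"):
        if name not in present:
            warnings.append(f"missing signature {name!r}: partial report")
    adj = alpha / n_comparisons

    if len(present) >= 3:
        apriori = friedman(*(present[k] for k in ("high", "all", "low")), alpha=alpha)
    else:
        apriori = TestResult("friedman", float("nan"), float("nan"),
                             0, alpha, degenerate=True)

    normality: dict[str, TestResult | None] = {}
    for name, vals in present.items():
        try:
            normality[name] = dagostino_normality(vals, alpha=alpha)
        except ValueError as exc:
            normality[name] = None
            warnings.append(f"normality pre-check failed for {name}: {exc}")
    normal_ok = all(r is not None and not r.significant for r in normality.values())
    location_test = "t-test" if normal_ok else "wilcoxon"

    pairwise_location: dict[str, TestResult] = {}
    pairwise_spread: dict[str, TestResult] = {}
    for other in ("high", "low"):
        label = f"{other}-vs-all"
        if other not in present or "all" not in present:
            continue
        a, b = present[other], present["all"]
        if location_test == "t-test":
            stat, p = sps.ttest_rel(a, b)
            pairwise_location[label] = TestResult("t-test", float(stat), float(p),
                                                  len(a), adj)
        else:
            pairwise_location[label] = wilcoxon_signed_rank(a, b, alpha=adj)
        try:
            pairwise_spread[label] = bartlett(a, b, alpha=adj)
        except ValueError as exc:
            warnings.append(f"Bartlett {label} skipped: {exc}")

    return SignatureComparison(
        friedman=apriori,
        pairwise_location=pairwise_location,
        pairwise_spread=pairwise_spread,
        normality=normality,
        location_test_used=location_test,
        means={k: float(v.mean()) for k, v in present.items()},
        sds={k: float(v.std(ddof=1)) for k, v in present.items()},
        warnings=warnings,
    )
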