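"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over definitions —
pair/run/zone/dependence enumeration, explicit ANOVA sums of squares,
textbook test statistics — and never calls the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

# --------------------------------------------------------------------------
# ICC(1): one-way ANOVA with explicit loops
# --------------------------------------------------------------------------

def icc1_anova_loops(matrix) -> float:
    m = [[float(v) for v in row] for row in matrix]
    n = len(m)
    k = len(m[0])
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    ssb = sum(k * (rm - grand) ** 2 for rm in row_means)
    ssw = 0.0
    for i in range(n):
        for j in range(k):
            ssw += (m[i][j] - row_means[i]) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 1.0
    return (msb - msw) / denom


# --------------------------------------------------------------------------
# Texture matrices by enumeration
# --------------------------------------------------------------------------

def glcm_pairs(levels, mask, offset, n_levels):
    """Symmetric co-occurrence counts by enumerating every pixel pair."""
    h, w = len(levels), len(levels[0])
    dy, dx = offset
    m = np.zeros((n_levels, n_levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y][x] and mask[y2][x2]:
                i, j = levels[y][x] - 1, levels[y2][x2] - 1
                m[i, j] += 1
                m[j, i] += 1
    return m


def glrlm_runs(levels, mask, offset, n_levels, max_len):
    """Run-length counts by walking each line pixel by pixel."""
    h, w = len(levels), len(levels[0])
    dy, dx = offset
    m = np.zeros((n_levels, max_len))
    starts = []
    for y in range(h):
        for x in range(w):
            py, px = y - dy, x - dx
            if not (0 <= py < h and 0 <= px < w):
                starts.append((y, x))
    for y0, x0 in starts:
        y, x = y0, x0
        run_level, run_len = 0, 0
        while 0 <= y < h and 0 <= x < w:
            lv = levels[y][x] if mask[y][x] else 0
            if lv == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    m[run_level - 1, run_len - 1] += 1
                run_level, run_len = lv, 1
            y, x = y + dy, x + dx
        if run_level > 0:
            m[run_level - 1, run_len - 1] += 1
    return m


def glszm_zones(levels, mask, n_levels, n_pixels):
    """Size-zone counts by explicit 8-connected flood fill."""
    h, w = len(levels), len(levels[0])
    seen = [[False] * w for _ in range(h)]
    m = np.zeros((n_levels, n_pixels))
    for y in range(h):
        for x in range(w):
            if not mask[y][x] or seen[y][x]:
                continue
            g = levels[y][x]
            stack = [(y, x)]
            seen[y][x] = True
            size = 0
            while stack:
                cy, cx = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < h and 0 <= nx < w and not seen[ny][nx]
                                and mask[ny][nx] and levels[ny][nx] == g):
                            seen[ny][nx] = True
                            stack.append((ny, nx))
            m[g - 1, size - 1] += 1
    return m


def gldm_dependences(levels, mask, n_levels):
    """Dependence counts: j = 1 + equal-level in-mask Chebyshev-1 neighbours."""
    h, w = len(levels), len(levels[0])
    m = np.zeros((n_levels, 10))
    for y in range(h):
        for x in range(w):
            if not mask[y][x]:
                continue
            dep = 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < h and 0 <= nx < w and mask[ny][nx]
                            and levels[ny][nx] == levels[y][x]):
                        dep += 1
            m[levels[y][x] - 1, dep] += 1
    return m


# --------------------------------------------------------------------------
# Harrell's C by pair enumeration
# --------------------------------------------------------------------------

def cindex_pairs(risk, time, event):
    num, den = 0.0, 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


# --------------------------------------------------------------------------
# Cox partial likelihood (Breslow) by loops
# --------------------------------------------------------------------------

def cox_loglik_loops(x, time, event, beta):
    """Breslow log partial likelihood, 1D covariate list, plain loops."""
    n = len(x)
    ll = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        risk_sum = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                risk_sum += math.exp(x[j] * beta)
        ll += x[i] * beta - math.log(risk_sum)
    return ll


# --------------------------------------------------------------------------
# Textbook test statistics
# --------------------------------------------------------------------------

def _rank_with_ties(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def friedman_statistic(groups):
    """Friedman chi-square with average ranks on ties (tie-corrected)."""
    k = len(groups)
    n = len(groups[0])
    rank_sums = [0.0] * k
    tie_correction = 0.0
    for b in range(n):
        block = [g[b] for g in groups]
        ranks = _rank_with_ties(block)
        for g in range(k):
            rank_sums[g] += ranks[g]
        # tie correction term sum(t^3 - t) within the block
        seen = {}
        for v in block:
            seen[v] = seen.get(v, 0) + 1
        tie_correction += sum(t**3 - t for t in seen.values())
    chi2 = (12.0 / (n * k * (k + 1))) * sum(r**2 for r in rank_sums) - 3.0 * n * (k + 1)
    c = 1.0 - tie_correction / (n * k * (k**2 - 1))
    return chi2 / c if c > 0 else float("nan")


def wilcoxon_exact_p(diffs):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = _rank_with_ties([abs(x) for x in d])
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    w_total = sum(ranks)
    count_le = 0
    count_ge = 0
    for pattern in range(2**n):
        w = sum(ranks[i] for i in range(n) if pattern >> i & 1)
        if w <= w_obs + 1e-12:
            count_le += 1
        if w >= w_obs - 1e-12:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / 2**n
    return min(p, 1.0)


def bartlett_statistic(groups):
    k = len(groups)
    ns = [len(g) for g in groups]
    n_total = sum(ns)
    variances = []
    for g in groups:
        mean = sum(g) / len(g)
        variances.append(sum((v - mean) ** 2 for v in g) / (len(g) - 1))
    sp2 = sum((ni - 1) * vi for ni, vi in zip(ns, variances)) / (n_total - k)
    num = (n_total - k) * math.log(sp2) - sum(
        (ni - 1) * math.log(vi) for ni, vi in zip(ns, variances))
    den = 1.0 + (sum(1.0 / (ni - 1) for ni in ns) - 1.0 / (n_total - k)) / (3.0 * (k - 1))
    return num / den


def dagostino_k2(sample):
    """D'Agostino-Pearson K^2 from the published z-transformations."""
    x = list(map(float, sample))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2 - 3.0

    # skewness z (D'Agostino 1970)
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    zs = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis z (Anscombe & Glynn 1983)
    eb2 = 3.0 * (n - 1) / (n + 1)
    vb2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    b2 = m4 / m2**2
    xx = (b2 - eb2) / math.sqrt(vb2)
    sqrtb1 = 6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9)) * math.sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    a = 6.0 + 8.0 / sqrtb1 * (2.0 / sqrtb1 + math.sqrt(1.0 + 4.0 / sqrtb1**2))
    zk = ((1.0 - 2.0 / (9.0 * a)) -
          ((1.0 - 2.0 / a) / (1.0 + xx * math.sqrt(2.0 / (a - 4.0)))) ** (1.0 / 3.0)
          ) / math.sqrt(2.0 / (9.0 * a))
    return zs**2 + zk**2


# --------------------------------------------------------------------------
# Texture features from enumerated matrices (formulas coded independently)
# --------------------------------------------------------------------------

def _entropy_bits(p):
    return -sum(v * math.log2(v) for v in np.ravel(p) if v > 0)


def glcm_features_from_matrix(counts):
    p = np.asarray(counts, float) / np.sum(counts)
    ng = p.shape[0]
    out = {}
    mu = 0.0
    px = p.sum(axis=1)
    for i in range(ng):
        mu += (i + 1) * px[i]
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    je = 0.0
    jent = _entropy_bits(p)
    contrast = dissim = idm = shade = prom = corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            je += v * v
            d = (i + 1) - (j + 1)
            contrast += d * d * v
            dissim += abs(d) * v
            idm += v / (1.0 + d * d)
            s = (i + 1) + (j + 1) - 2 * mu
            shade += s**3 * v
            prom += s**4 * v
            corr_num += (i + 1) * (j + 1) * v
    corr = (corr_num - mu * mu) / var if var > 0 else 1.0
    return {"JointEnergy": je, "JointEntropy": jent, "Contrast": contrast,
            "Dissimilarity": dissim, "InverseDifferenceMoment": idm,
            "Correlation": corr, "ClusterShade": shade,
            "ClusterProminence": prom}


def rlm_features_from_matrix(counts, n_pixels, kind):
    m = np.asarray(counts, float)
    n_runs = m.sum()
    ng, nl = m.shape
    r_g = m.sum(axis=1)
    r_l = m.sum(axis=0)
    sre = sum(r_l[j] / (j + 1) ** 2 for j in range(nl)) / n_runs
    lre = sum(r_l[j] * (j + 1) ** 2 for j in range(nl)) / n_runs
    gln = sum(v * v for v in r_g) / n_runs
    rln = sum(v * v for v in r_l) / n_runs
    lgl = sum(r_g[i] / (i + 1) ** 2 for i in range(ng)) / n_runs
    hgl = sum(r_g[i] * (i + 1) ** 2 for i in range(ng)) / n_runs
    ent = _entropy_bits(m / n_runs)
    if kind == "run":
        return {"ShortRunEmphasis": sre, "LongRunEmphasis": lre,
                "GrayLevelNonUniformity": gln, "RunLengthNonUniformity": rln,
                "RunPercentage": n_runs / n_pixels,
                "LowGrayLevelRunEmphasis": lgl,
                "HighGrayLevelRunEmphasis": hgl, "RunEntropy": ent}
    return {"SmallAreaEmphasis": sre, "LargeAreaEmphasis": lre,
            "GrayLevelNonUniformity": gln, "SizeZoneNonUniformity": rln,
            "ZonePercentage": n_runs / n_pixels,
            "LowGrayLevelZoneEmphasis": lgl,
            "HighGrayLevelZoneEmphasis": hgl, "ZoneEntropy": ent}


def gldm_features_from_matrix(counts):
    m = np.asarray(counts, float)
    n = m.sum()
    ng, nd = m.shape
    d_g = m.sum(axis=1)
    d_j = m.sum(axis=0)
    mu_j = sum((j + 1) * d_j[j] for j in range(nd)) / n
    return {
        "SmallDependenceEmphasis": sum(d_j[j] / (j + 1) ** 2 for j in range(nd)) / n,
        "LargeDependenceEmphasis": sum(d_j[j] * (j + 1) ** 2 for j in range(nd)) / n,
        "GrayLevelNonUniformity": sum(v * v for v in d_g) / n,
        "DependenceNonUniformity": sum(v * v for v in d_j) / n,
        "DependenceEntropy": _entropy_bits(m / n),
        "DependenceVariance": sum((j + 1 - mu_j) ** 2 * d_j[j] for j in range(nd)) / n,
        "LowGrayLevelEmphasis": sum(d_g[i] / (i + 1) ** 2 for i in range(ng)) / n,
        "HighGrayLevelEmphasis": sum(d_g[i] * (i + 1) ** 2 for i in range(ng)) / n,
    }
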