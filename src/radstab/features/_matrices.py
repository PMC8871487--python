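"""Gray-level texture matrices: co-occurrence, run-length, size-zone, dependence.

All operate on a discretized gray-level image (integer levels 1..Ng in-mask,
0 outside the mask).  Directional matrices (GLCM, GLRLM) use the four 2D
directions at distance 1 — 0°, 45°, 90°, 135° — with features computed per
direction and averaged, which makes the averaged features exactly invariant
under 90° rotations.  Zones use 8-connectivity; dependence uses the distance-1
Chebyshev neighbourhood with an equality criterion (alpha = 0).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).tiny

# (dy, dx) offsets for 0°, 45°, 90°, 135°
_DIRECTIONS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def _entropy2(p: np.ndarray) -> float:
    pz = p[p > 0]
    return float(-np.sum(pz * np.log2(pz)))


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
                n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one offset (unnormalized)."""
    mask = np.asarray(mask, bool)
    lv = np.where(mask, levels, 0)
    dy, dx = offset
    h, w = lv.shape
    src = lv[max(0, -dy):h - max(0, dy), max(0, -dx):w - max(0, dx)]
    dst = lv[max(0, dy):h - max(0, -dy), max(0, dx):w - max(0, -dx)]
    valid = (src > 0) & (dst > 0)
    i = src[valid] - 1
    j = dst[valid] - 1
    m = np.bincount(i * n_levels + j,
                    minlength=n_levels * n_levels).reshape(n_levels, n_levels).astype(float)
    return m + m.T  # symmetric


_GRIDS: dict[int, tuple] = {}


def _grids(ng: int):
    if ng not in _GRIDS:
        i = np.arange(1, ng + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        _GRIDS[ng] = (i, ii, jj, (ii - jj) ** 2, np.abs(ii - jj))
    return _GRIDS[ng]


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i, ii, jj, diff2, absdiff = _grids(ng)
    px = p.sum(axis=1)
    mu_x = float(np.sum(i * px))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    # symmetric matrix: marginals coincide
    if sig_x > 0:
        corr = float((np.sum(ii * jj * p) - mu_x * mu_x) / (sig_x * sig_x))
    else:
        corr = 1.0  # constant region, by convention
    s = ii + jj - 2 * mu_x
    s3 = s * s * s
    return {
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": _entropy2(p),
        "Contrast": float(np.sum(diff2 * p)),
        "Dissimilarity": float(np.sum(absdiff * p)),
        "InverseDifferenceMoment": float(np.sum(p / (1.0 + diff2))),
        "Correlation": corr,
        "ClusterShade": float(np.sum(s3 * p)),
        "ClusterProminence": float(np.sum(s3 * s * p)),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged co-occurrence features (distance 1, symmetric)."""
    if np.asarray(mask, bool).sum() < 2:
        raise ValueError("GLCM needs at least two in-mask pixels")
    per_dir = []
    for off in _DIRECTIONS:
        m = glcm_matrix(levels, mask, off, n_levels)
        tot = m.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_features_one(m / tot))
    if not per_dir:
        raise ValueError("no valid pixel pairs for any direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def _direction_lines(arr: np.ndarray, offset: tuple[int, int]) -> list[np.ndarray]:
    dy, dx = offset
    if (dy, dx) == (0, 1):
        return [arr[r] for r in range(arr.shape[0])]
    if (dy, dx) == (-1, 0):
        return [arr[:, c] for c in range(arr.shape[1])]
    if (dy, dx) == (-1, 1):  # 45 deg: anti-diagonals
        flipped = arr[:, ::-1]
        return [flipped.diagonal(k) for k in range(-arr.shape[0] + 1, arr.shape[1])]
    if (dy, dx) == (-1, -1):  # 135 deg: main diagonals
        return [arr.diagonal(k) for k in range(-arr.shape[0] + 1, arr.shape[1])]
    raise ValueError(f"unsupported offset {offset}")


def _run_lengths(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(gray level, run length) of every maximal run; level-0 gaps dropped."""
    parts: list[np.ndarray] = []
    sep = np.zeros(1, dtype=int)
    for line in lines:
        parts.append(np.asarray(line, int))
        parts.append(sep)
    v = np.concatenate(parts)
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(v)]))
    vals = v[starts]
    lens = ends - starts
    keep = vals > 0
    return vals[keep], lens[keep]


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
                 n_levels: int) -> np.ndarray:
    """Run-length count matrix R[g-1, l-1] for one direction."""
    lv = np.where(np.asarray(mask, bool), levels, 0)
    vals, lens = _run_lengths(_direction_lines(lv, offset))
    max_len = max(lv.shape)
    m = np.zeros((n_levels, max_len))
    if len(vals):
        np.add.at(m, (vals - 1, lens - 1), 1)
    return m


def _rlm_like_features(m: np.ndarray, n_pixels: int, prefix: str) -> dict[str, float]:
    """Shared emphasis/non-uniformity formulas for run- and zone-type matrices."""
    n_runs = m.sum()
    i = np.arange(1, m.shape[0] + 1)
    j = np.arange(1, m.shape[1] + 1)
    r_g = m.sum(axis=1)
    r_l = m.sum(axis=0)
    p = m / n_runs
    small, large, glne_lo, glne_hi, gln, sizenu, pct, ent = _PREFIX_NAMES[prefix]
    return {
        small: float(np.sum(r_l / j**2) / n_runs),
        large: float(np.sum(r_l * j**2) / n_runs),
        gln: float(np.sum(r_g**2) / n_runs),
        sizenu: float(np.sum(r_l**2) / n_runs),
        pct: float(n_runs / n_pixels),
        glne_lo: float(np.sum(r_g / i**2) / n_runs),
        glne_hi: float(np.sum(r_g * i**2) / n_runs),
        ent: _entropy2(p),
    }


_PREFIX_NAMES = {
    "run": ("ShortRunEmphasis", "LongRunEmphasis", "LowGrayLevelRunEmphasis",
            "HighGrayLevelRunEmphasis", "GrayLevelNonUniformity",
            "RunLengthNonUniformity", "RunPercentage", "RunEntropy"),
    "zone": ("SmallAreaEmphasis", "LargeAreaEmphasis", "LowGrayLevelZoneEmphasis",
             "HighGrayLevelZoneEmphasis", "GrayLevelNonUniformity",
             "SizeZoneNonUniformity", "ZonePercentage", "ZoneEntropy"),
}


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged run-length features."""
    n_pixels = int(np.asarray(mask, bool).sum())
    if n_pixels == 0:
        raise ValueError("mask is empty")
    per_dir = []
    for off in _DIRECTIONS:
        m = glrlm_matrix(levels, mask, off, n_levels)
        if m.sum() == 0:
            continue
        per_dir.append(_rlm_like_features(m, n_pixels, "run"))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix Z[g-1, s-1]; zones are 8-connected equal-level areas."""
    mask = np.asarray(mask, bool)
    lv = np.where(mask, levels, 0)
    n_pixels = int(mask.sum())
    m = np.zeros((n_levels, n_pixels))
    for g in np.unique(lv[mask]):
        labels, n = ndimage.label(lv == g, structure=_STRUCT8)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        np.add.at(m, (np.full(n, g - 1), sizes - 1), 1)
    return m


def glszm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Size-zone features (single isotropic matrix)."""
    n_pixels = int(np.asarray(mask, bool).sum())
    if n_pixels == 0:
        raise ValueError("mask is empty")
    m = glszm_matrix(levels, mask, n_levels)
    return _rlm_like_features(m, n_pixels, "zone")


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence count matrix D[g-1, j-1].

    The dependence size j of a pixel is 1 plus the number of in-mask
    Chebyshev-distance-1 neighbours sharing its gray level (alpha = 0), so
    j ranges over 1..9 in 2D.
    """
    mask = np.asarray(mask, bool)
    lv = np.where(mask, levels, 0)
    h, w = lv.shape
    dep = np.zeros_like(lv)
    for dy, dx in _NEIGHBORS8:
        shifted = np.zeros_like(lv)
        src = lv[max(0, -dy):h - max(0, dy), max(0, -dx):w - max(0, dx)]
        shifted[max(0, dy):h - max(0, -dy), max(0, dx):w - max(0, -dx)] = src
        dep += ((shifted == lv) & (shifted > 0)).astype(int)
    j = np.where(mask, dep + 1, 0)
    m = np.zeros((n_levels, 10))
    np.add.at(m, (lv[mask] - 1, j[mask] - 1), 1)
    return m


def gldm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Gray-level dependence features."""
    n_pixels = int(np.asarray(mask, bool).sum())
    if n_pixels == 0:
        raise ValueError("mask is empty")
    m = gldm_matrix(levels, mask, n_levels)
    n = m.sum()  # == n_pixels
    i = np.arange(1, m.shape[0] + 1)
    j = np.arange(1, m.shape[1] + 1)
    d_g = m.sum(axis=1)
    d_j = m.sum(axis=0)
    p = m / n
    p_j = d_j / n
    mu_j = float(np.sum(j * p_j))
    return {
        "SmallDependenceEmphasis": float(np.sum(d_j / j**2) / n),
        "LargeDependenceEmphasis": float(np.sum(d_j * j**2) / n),
        "GrayLevelNonUniformity": float(np.sum(d_g**2) / n),
        "DependenceNonUniformity": float(np.sum(d_j**2) / n),
        "DependenceEntropy": _entropy2(p),
        "DependenceVariance": float(np.sum((j - mu_j) ** 2 * p_j)),
        "LowGrayLevelEmphasis": float(np.sum(d_g / i**2) / n),
        "HighGrayLevelEmphasis": float(np.sum(d_g * i**2) / n),
    }
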