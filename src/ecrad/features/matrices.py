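"""Gray-level matrix builders (GLCM, GLRLM, GLSZM, NGTDM) and their features.

Builders accept an integer level array plus a boolean ROI mask and work for
both 2D sections and 3D volumes; out-of-mask voxels never contribute.

Conventions shared across the module:

* GLCM is symmetric, distance 1, accumulated over 4 directions (2D) or
  13 directions (3D) into a single count matrix.
* GLRLM features are computed per direction and averaged over directions.
* GLSZM zones use 8-connectivity (2D) / 26-connectivity (3D).
* Gray-level weights use ``i + 1`` where a division by the level appears
  (levels start at 0; the shift keeps low-gray emphasis finite).
* Degenerate denominators (zero variance, empty matrices) yield 0 so
  feature vectors are always finite; ``0 * log 0`` terms are 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def offsets_2d() -> list[tuple[int, int]]:
    """The 4 unique direction offsets of the 8-neighborhood (up to sign)."""
    return [(0, 1), (1, 0), (1, 1), (1, -1)]


def offsets_3d() -> list[tuple[int, int, int]]:
    """The 13 unique direction offsets of the 26-neighborhood (up to sign)."""
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                first = next(v for v in d if v != 0)
                if first > 0:
                    out.append(d)
    assert len(out) == 13
    return out


def default_offsets(ndim: int):
    return offsets_2d() if ndim == 2 else offsets_3d()


def _shift(arr: np.ndarray, offset, fill) -> np.ndarray:
    """Return ``out[x] = arr[x + offset]`` with out-of-bounds set to fill."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, d in zip(arr.shape, offset):
        if d >= 0:
            dst.append(slice(0, n - d))
            src.append(slice(d, n))
        else:
            dst.append(slice(-d, n))
            src.append(slice(0, n + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                offsets=None, distance: int = 1) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts accumulated over offsets."""
    mask = mask.astype(bool)
    if offsets is None:
        offsets = default_offsets(levels.ndim)
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for off in offsets:
        off = tuple(int(d) * distance for d in off)
        nb_mask = _shift(mask, off, False)
        nb_levels = _shift(levels, off, -1)
        both = mask & nb_mask
        i = levels[both]
        j = nb_levels[both]
        np.add.at(counts, (i, j), 1)
        np.add.at(counts, (j, i), 1)
    return counts


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """The 19 co-occurrence features used by the 3D branch (2D uses a subset)."""
    total = counts.sum()
    n = counts.shape[0]
    if total == 0:
        return {k: 0.0 for k in _GLCM_KEYS}
    p = counts / total
    i, j = np.indices(p.shape)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lv = np.arange(n)
    mu_x = (lv * px).sum()
    mu_y = (lv * py).sum()
    sd_x = np.sqrt(((lv - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((lv - mu_y) ** 2 * py).sum())

    def xlog2(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    # sum / difference marginals
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())
    ks = np.arange(2 * n - 1)
    kd = np.arange(n)
    sum_avg = (ks * p_sum).sum()
    diff_avg = (kd * p_diff).sum()

    if sd_x > 0 and sd_y > 0:
        correlation = (((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y)
    else:
        correlation = 0.0

    hxy = -xlog2(p).sum()
    hx = -xlog2(px).sum()
    hy = -xlog2(py).sum()
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = -(p * log_pxy).sum()
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0

    off_diag = i != j
    inv_var = (p[off_diag] / (i[off_diag] - j[off_diag]) ** 2).sum()

    return {
        "Energy": float((p ** 2).sum()),
        "Contrast": float(((i - j) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "Homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Entropy": float(hxy),
        "Dissimilarity": float((np.abs(i - j) * p).sum()),
        "Autocorrelation": float((i * j * p).sum()),
        "ClusterShade": float((((i + j) - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterProminence": float((((i + j) - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterTendency": float((((i + j) - mu_x - mu_y) ** 2 * p).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(sum_avg),
        "SumEntropy": float(-xlog2(p_sum).sum()),
        "SumVariance": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "DifferenceEntropy": float(-xlog2(p_diff).sum()),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "InverseDifference": float((p / (1.0 + np.abs(i - j))).sum()),
        "InverseVariance": float(inv_var),
        "IMC1": float(imc1),
    }


_GLCM_KEYS = list(glcm_features(np.ones((2, 2), dtype=np.int64)).keys())


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                 offset) -> np.ndarray:
    """Run-length counts P(i, j) for one direction; column j = run length j+1.

    A run is a maximal straight sequence of in-mask voxels sharing one gray
    level along ``offset``.
    """
    mask = mask.astype(bool)
    same_next = mask & _shift(mask, offset, False) & \
        (levels == _shift(levels, offset, np.int64(-2)))
    # f[x] = remaining run length starting at x (1 + f at the next voxel)
    f = mask.astype(np.int64)
    while True:
        f_new = np.where(same_next, 1 + _shift(f, offset, 0), mask.astype(np.int64))
        if np.array_equal(f_new, f):
            break
        f = f_new
    neg = tuple(-d for d in offset)
    same_prev = _shift(same_next, neg, False)
    starts = mask & ~same_prev
    run_levels = levels[starts]
    run_lengths = f[starts]
    max_len = int(run_lengths.max()) if run_lengths.size else 1
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    np.add.at(counts, (run_levels, run_lengths - 1), 1)
    return counts


def _rl_style_features(counts: np.ndarray, n_voxels: int,
                       names: dict[str, str]) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``counts[i, j]`` is the number of runs (zones) of gray level i and
    length (size) j+1.  Gray-level weights use i+1, length weights j+1.
    """
    n_runs = counts.sum()
    keys = list(names.values())
    if n_runs == 0:
        return {k: 0.0 for k in keys}
    gi = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    rj = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    c = counts.astype(float)
    p = c / n_runs
    mu_g = (gi * p).sum()
    mu_r = (rj * p).sum()
    out = {
        "short_emphasis": (c / rj ** 2).sum() / n_runs,
        "long_emphasis": (c * rj ** 2).sum() / n_runs,
        "gray_nonuniformity": (c.sum(axis=1) ** 2).sum() / n_runs,
        "length_nonuniformity": (c.sum(axis=0) ** 2).sum() / n_runs,
        "percentage": n_runs / n_voxels,
        "low_gray_emphasis": (c / gi ** 2).sum() / n_runs,
        "high_gray_emphasis": (c * gi ** 2).sum() / n_runs,
        "short_low_gray": (c / (gi ** 2 * rj ** 2)).sum() / n_runs,
        "short_high_gray": (c * gi ** 2 / rj ** 2).sum() / n_runs,
        "long_low_gray": (c * rj ** 2 / gi ** 2).sum() / n_runs,
        "long_high_gray": (c * gi ** 2 * rj ** 2).sum() / n_runs,
        "gray_variance": ((gi - mu_g) ** 2 * p).sum(),
        "length_variance": ((rj - mu_r) ** 2 * p).sum(),
    }
    return {names[k]: float(v) for k, v in out.items()}


_GLRLM_NAMES = {
    "short_emphasis": "SRE", "long_emphasis": "LRE", "gray_nonuniformity": "GLN",
    "length_nonuniformity": "RLN", "percentage": "RP",
    "low_gray_emphasis": "LGRE", "high_gray_emphasis": "HGRE",
    "short_low_gray": "SRLGE", "short_high_gray": "SRHGE",
    "long_low_gray": "LRLGE", "long_high_gray": "LRHGE",
    "gray_variance": "GLV", "length_variance": "RLV",
}
_GLSZM_NAMES = {
    "short_emphasis": "SZE", "long_emphasis": "LZE", "gray_nonuniformity": "GLN",
    "length_nonuniformity": "ZSN", "percentage": "ZP",
    "low_gray_emphasis": "LGZE", "high_gray_emphasis": "HGZE",
    "short_low_gray": "SZLGE", "short_high_gray": "SZHGE",
    "long_low_gray": "LZLGE", "long_high_gray": "LZHGE",
    "gray_variance": "GLV", "length_variance": "ZSV",
}


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                   offsets=None) -> dict[str, float]:
    """Run-length features, averaged over the direction set."""
    mask = mask.astype(bool)
    if offsets is None:
        offsets = default_offsets(levels.ndim)
    n_vox = int(mask.sum())
    per_dir = [
        _rl_style_features(glrlm_matrix(levels, mask, n_levels, off),
                           n_vox, _GLRLM_NAMES)
        for off in offsets
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(levels: np.ndarray, mask: np.ndarray,
                 n_levels: int) -> np.ndarray:
    """Size-zone counts: connected components of equal gray level.

    Connectivity is full (8 in 2D, 26 in 3D).
    """
    mask = mask.astype(bool)
    structure = np.ones((3,) * levels.ndim, dtype=bool)
    zone_sizes: list[tuple[int, int]] = []
    present = np.unique(levels[mask]) if mask.any() else []
    for lvl in present:
        lab, n_zones = ndimage.label((levels == lvl) & mask, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes.extend((int(lvl), int(s)) for s in sizes)
    max_size = max((s for _, s in zone_sizes), default=1)
    counts = np.zeros((n_levels, max_size), dtype=np.int64)
    for lvl, s in zone_sizes:
        counts[lvl, s - 1] += 1
    return counts


def glszm_features(levels: np.ndarray, mask: np.ndarray,
                   n_levels: int) -> dict[str, float]:
    mask = mask.astype(bool)
    counts = glszm_matrix(levels, mask, n_levels)
    return _rl_style_features(counts, int(mask.sum()), _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_table(levels: np.ndarray, mask: np.ndarray,
                n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts ``n_i`` and gray-tone difference sums ``s_i``.

    For every in-mask voxel with at least one in-mask neighbour (full 8/26
    neighbourhood), the absolute difference between its level and the mean
    level of those neighbours is accumulated into its level's bin.
    """
    mask = mask.astype(bool)
    kernel = np.ones((3,) * levels.ndim)
    kernel[(1,) * levels.ndim] = 0
    lv = np.where(mask, levels, 0).astype(float)
    nb_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant",
                              cval=0.0)
    valid = mask & (nb_cnt > 0)
    diffs = np.zeros_like(lv)
    diffs[valid] = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(levels[valid], minlength=n_levels).astype(float)
    s_i = np.bincount(levels[valid], weights=diffs[valid],
                      minlength=n_levels)
    return n_i, s_i


def ngtdm_features(levels: np.ndarray, mask: np.ndarray,
                   n_levels: int) -> dict[str, float]:
    n_i, s_i = ngtdm_table(levels, mask, n_levels)
    n_total = n_i.sum()
    zeros = {k: 0.0 for k in NGTDM_KEYS}
    if n_total == 0:
        return zeros
    p_i = n_i / n_total
    present = p_i > 0
    ng = int(present.sum())
    lv = np.arange(n_levels, dtype=float)

    ps = (p_i * s_i).sum()
    coarseness = 1.0 / ps if ps > 0 else 0.0

    if ng > 1:
        ii, jj = np.meshgrid(lv[present], lv[present], indexing="ij")
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        contrast = (pi_ * pj_ * (ii - jj) ** 2).sum() / (ng * (ng - 1)) \
            * s_i.sum() / n_total
        busy_den = np.abs(ii * pi_ - jj * pj_).sum()
        busyness = ps / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = (np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_)
                      / (pi_ + pj_)).sum() / n_total
        strength_num = ((pi_ + pj_) * (ii - jj) ** 2).sum()
        s_tot = s_i.sum()
        strength = strength_num / s_tot if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


NGTDM_KEYS = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
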