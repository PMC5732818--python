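"""Gray-level gradient co-occurrence matrix (GLGCM) features — 2D only.

The GLGCM is the joint histogram of quantized gray level and quantized
Sobel gradient magnitude over ROI pixels whose full 3x3 Sobel stencil lies
inside the ROI ("interior" pixels).  The gradient magnitude is min–max
quantized to 16 bins over those interior pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

N_GRADIENT_BINS = 16

GLGCM_KEYS = [
    "SmallGradientEmphasis", "LargeGradientEmphasis", "GrayNonuniformity",
    "GradientNonuniformity", "Energy", "Correlation", "GrayEntropy",
    "GradientEntropy", "GradientMean", "GradientVariance",
]


def glgcm_matrix(levels: np.ndarray, mask: np.ndarray,
                 n_levels: int) -> np.ndarray:
    """Joint counts H[level, gradient_bin] over interior ROI pixels."""
    if levels.ndim != 2:
        raise ValueError("GLGCM is defined on 2D sections only")
    mask = mask.astype(bool)
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    counts = np.zeros((n_levels, N_GRADIENT_BINS), dtype=np.int64)
    if not interior.any():
        return counts
    lv = np.where(mask, levels, 0).astype(float)
    gx = ndimage.sobel(lv, axis=0, mode="constant")
    gy = ndimage.sobel(lv, axis=1, mode="constant")
    gmag = np.sqrt(gx ** 2 + gy ** 2)
    g = gmag[interior]
    lo, hi = g.min(), g.max()
    if hi == lo:
        gq = np.zeros(g.shape, dtype=np.int64)
    else:
        gq = np.minimum(
            np.floor(N_GRADIENT_BINS * (g - lo) / (hi - lo)).astype(np.int64),
            N_GRADIENT_BINS - 1)
    np.add.at(counts, (levels[interior], gq), 1)
    return counts


def glgcm_features(levels: np.ndarray, mask: np.ndarray,
                   n_levels: int) -> dict[str, float]:
    counts = glgcm_matrix(levels, mask, n_levels)
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in GLGCM_KEYS}
    c = counts.astype(float)
    p = c / total
    gi = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]  # gray, 1-based
    gj = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]  # gradient
    p_gray = p.sum(axis=1)
    p_grad = p.sum(axis=0)
    mu_i = (gi[:, 0] * p_gray).sum()
    mu_j = (gj[0] * p_grad).sum()
    sd_i = np.sqrt(((gi[:, 0] - mu_i) ** 2 * p_gray).sum())
    sd_j = np.sqrt(((gj[0] - mu_j) ** 2 * p_grad).sum())
    if sd_i > 0 and sd_j > 0:
        corr = (((gi - mu_i) * (gj - mu_j) * p).sum()) / (sd_i * sd_j)
    else:
        corr = 0.0

    def entropy(q):
        nz = q[q > 0]
        return float(-(nz * np.log2(nz)).sum())

    return {
        "SmallGradientEmphasis": float((c / gj ** 2).sum() / total),
        "LargeGradientEmphasis": float((c * gj ** 2).sum() / total),
        "GrayNonuniformity": float((c.sum(axis=1) ** 2).sum() / total),
        "GradientNonuniformity": float((c.sum(axis=0) ** 2).sum() / total),
        "Energy": float((p ** 2).sum()),
        "Correlation": float(corr),
        "GrayEntropy": entropy(p_gray),
        "GradientEntropy": entropy(p_grad),
        "GradientMean": float(mu_j),
        "GradientVariance": float(sd_j ** 2),
    }
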