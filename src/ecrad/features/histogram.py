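"""First-order (histogram) statistics of ROI values.

Six statistics: mean, variance, skewness (third standardized moment),
kurtosis (Pearson, non-excess), energy (sum of squared histogram
probabilities) and Shannon entropy (bits) of the level histogram.

Zero-variance input uses the conventions skewness = kurtosis = 0 so
feature vectors stay finite.
"""

from __future__ import annotations

import numpy as np


def first_order_stats(values: np.ndarray, n_bins: int,
                      discrete: bool = True) -> dict[str, float]:
    """Six first-order statistics of a 1D sample.

    ``discrete=True`` treats values as integer levels in ``[0, n_bins)``
    and bins them directly; otherwise values are min–max binned into
    ``n_bins`` equal-width bins (used for filtered-image statistics).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    mean = values.mean()
    var = values.var()  # population variance
    if var > 0:
        z = (values - mean) / np.sqrt(var)
        skewness = float((z ** 3).mean())
        kurtosis = float((z ** 4).mean())
    else:
        skewness = 0.0
        kurtosis = 0.0
    if discrete:
        counts = np.bincount(values.astype(np.int64), minlength=n_bins)
    else:
        lo, hi = values.min(), values.max()
        if hi == lo:
            counts = np.zeros(n_bins, dtype=np.int64)
            counts[0] = values.size
        else:
            counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    nz = p[p > 0]
    return {
        "mean": float(mean),
        "variance": float(var),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "energy": float((p ** 2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
    }


def histogram_features(levels: np.ndarray, mask: np.ndarray,
                       n_levels: int) -> dict[str, float]:
    """First-order statistics of the quantized in-mask levels."""
    return first_order_stats(levels[mask.astype(bool)], n_levels, discrete=True)
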