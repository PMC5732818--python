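"""Transform-domain 2D features: Laplacian-of-Gaussian and Gabor banks.

Both operate on the raw (resampled, unquantized) intensities of the largest
axial tumor section; statistics are restricted to in-mask pixels.

* LoG: sigmas 1.0 / 2.0 / 2.5 mm highlight fine, medium and coarse texture;
  for each sigma the six first-order statistics of the filtered in-mask
  values are reported (continuous values, 16-bin min–max histogram for
  energy/entropy).
* Gabor: 5 scales x 8 orientations.  Center frequencies are log-spaced
  over 0.05–0.4 cycles/pixel (scale index 1 = coarsest), orientations are
  (o-1)*pi/8.  Per filter: MSA = mean complex-response magnitude over
  in-mask pixels; MSE = Shannon entropy (bits) of the 16-bin min–max
  histogram of those magnitudes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from .histogram import first_order_stats
from .manifest import LOG_SIGMAS, GABOR_N_SCALES, GABOR_N_ORIENTATIONS

GABOR_FREQ_RANGE = (0.05, 0.4)
HIST_BINS = 16


def log_features(section: np.ndarray, mask: np.ndarray,
                 sigmas=tuple(LOG_SIGMAS)) -> dict[str, float]:
    """First-order statistics of LoG-filtered in-mask values per sigma."""
    if section.ndim != 2:
        raise ValueError("LoG features are defined on 2D sections only")
    mask = mask.astype(bool)
    out: dict[str, float] = {}
    for sigma in sigmas:
        filtered = ndimage.gaussian_laplace(section.astype(float), sigma,
                                            mode="nearest")
        stats = first_order_stats(filtered[mask], HIST_BINS, discrete=False)
        for stat, value in stats.items():
            out[f"sigma{sigma:g}_{stat}"] = value
    return out


@lru_cache(maxsize=1)
def gabor_bank() -> list[tuple[int, int, np.ndarray]]:
    """The 40-filter bank as (scale_index, orientation_index, kernel)."""
    freqs = np.geomspace(GABOR_FREQ_RANGE[0], GABOR_FREQ_RANGE[1],
                         GABOR_N_SCALES)
    bank = []
    for s, freq in enumerate(freqs, start=1):
        for o in range(1, GABOR_N_ORIENTATIONS + 1):
            theta = (o - 1) * np.pi / GABOR_N_ORIENTATIONS
            bank.append((s, o, gabor_kernel(freq, theta=theta, bandwidth=1.0)))
    return bank


def gabor_features(section: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """MSA / MSE for every filter in the 5x8 Gabor bank."""
    if section.ndim != 2:
        raise ValueError("Gabor features are defined on 2D sections only")
    mask = mask.astype(bool)
    sec = section.astype(float)
    out: dict[str, float] = {}
    for s, o, kernel in gabor_bank():
        resp = fftconvolve(sec, kernel, mode="same")
        mag = np.abs(resp)[mask]
        out[f"MSA-{s}{o}"] = float(mag.mean())
        lo, hi = mag.min(), mag.max()
        if hi == lo:
            entropy = 0.0
        else:
            counts, _ = np.histogram(mag, bins=HIST_BINS, range=(lo, hi))
            p = counts / counts.sum()
            nz = p[p > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
        out[f"MSE-{s}{o}"] = entropy
    return out
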