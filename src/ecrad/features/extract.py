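"""Per-case feature extraction: preprocessing plus all feature families.

``extract_all`` takes one case, resamples it to isotropic voxels, quantizes
the ROI and evaluates every family on the 3D ROI and on the largest axial
section, returning the manifest's 214 values in canonical order.

Quantization for the 2D branch is recomputed over the section's pixels
(the ROI for a 2D feature is the section itself), so 2D histograms span
the full level range of the section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..preprocess import (
    ImageVolume, largest_axial_section, quantize_gray_levels,
    resample_isotropic,
)
from ..synthetic_cohort import PatientCase
from . import glgcm, matrices, transforms
from .histogram import histogram_features
from .manifest import GLCM_FEATURES_2D, feature_manifest
from .shape import shape_features


@dataclass
class ExtractionConfig:
    """Preprocessing / extraction settings (defaults are the reporting setup)."""

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    k_bits: int = 4  # 16 gray levels
    interpolation_order: int = 3


def _crop_to_mask(data: np.ndarray, mask: np.ndarray, margin: int = 2):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return data[sl], mask[sl]


def extract_all(case: PatientCase, config: ExtractionConfig | None = None,
                observer: int = 1) -> dict[str, float]:
    """Extract the full 214-feature vector for one case.

    ``observer`` selects the contour: 1 = primary, 2 = secondary.
    """
    config = config or ExtractionConfig()
    if observer == 1:
        mask = case.mask_primary
    elif observer == 2:
        if case.mask_secondary is None:
            raise ValueError(f"case {case.case_id} has no secondary contour")
        mask = case.mask_secondary
    else:
        raise ValueError(f"observer must be 1 or 2, got {observer}")

    try:
        volume = ImageVolume(np.asarray(case.volume, dtype=float), case.spacing)
        vol_iso, mask_iso = resample_isotropic(
            volume, mask, config.target_spacing, order=config.interpolation_order)
        data, roi = _crop_to_mask(vol_iso.data, mask_iso)
        n_levels = 2 ** config.k_bits

        values: dict[str, float] = {}

        # ---- 3D branch ----------------------------------------------
        q3 = quantize_gray_levels(data, roi, k=config.k_bits, dimensionality="3D")
        for k, v in shape_features(roi, vol_iso.spacing).items():
            values[f"Shape3D_{k}"] = v
        for k, v in histogram_features(q3.levels, roi, n_levels).items():
            values[f"Histogram3D_{k}"] = v
        glcm3 = matrices.glcm_matrix(q3.levels, roi, n_levels)
        for k, v in matrices.glcm_features(glcm3).items():
            values[f"GLCM3D_{k}"] = v
        for k, v in matrices.glrlm_features(q3.levels, roi, n_levels).items():
            values[f"GLRLM3D_{k}"] = v
        for k, v in matrices.glszm_features(q3.levels, roi, n_levels).items():
            values[f"GLSZM3D_{k}"] = v
        for k, v in matrices.ngtdm_features(q3.levels, roi, n_levels).items():
            values[f"NGTDM3D_{k}"] = v

        # ---- 2D branch: largest axial section -----------------------
        z = largest_axial_section(roi)
        sec = data[:, :, z]
        sec_mask = roi[:, :, z]
        q2 = quantize_gray_levels(sec, sec_mask, k=config.k_bits,
                                  dimensionality="2D")
        for k, v in histogram_features(q2.levels, sec_mask, n_levels).items():
            values[f"Histogram2D_{k}"] = v
        glcm2 = matrices.glcm_matrix(q2.levels, sec_mask, n_levels)
        feats2 = matrices.glcm_features(glcm2)
        for k in GLCM_FEATURES_2D:
            values[f"GLCM2D_{k}"] = feats2[k]
        for k, v in matrices.glrlm_features(q2.levels, sec_mask, n_levels).items():
            values[f"GLRLM2D_{k}"] = v
        for k, v in matrices.glszm_features(q2.levels, sec_mask, n_levels).items():
            values[f"GLSZM2D_{k}"] = v
        for k, v in matrices.ngtdm_features(q2.levels, sec_mask, n_levels).items():
            values[f"NGTDM2D_{k}"] = v
        for k, v in glgcm.glgcm_features(q2.levels, sec_mask, n_levels).items():
            values[f"GLGCM2D_{k}"] = v
        for k, v in transforms.log_features(sec, sec_mask).items():
            values[f"LoG2D_{k}"] = v
        for k, v in transforms.gabor_features(sec, sec_mask).items():
            values[f"Gabor2D_{k}"] = v
    except Exception as exc:
        raise RuntimeError(
            f"feature extraction failed for case {case.case_id}: {exc}") from exc

    manifest = feature_manifest()
    ordered = {name: float(values[name]) for name in manifest.names}
    bad = [n for n, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(
            f"case {case.case_id}: non-finite features {bad[:5]}")
    return ordered


def extract_table(cases: list[PatientCase],
                  config: ExtractionConfig | None = None,
                  observer: int = 1) -> pd.DataFrame:
    """Feature table (rows = cases, columns = manifest order).

    When ``observer=2``, cases without a secondary contour are skipped.
    """
    rows = {}
    for case in cases:
        if observer == 2 and case.mask_secondary is None:
            continue
        rows[case.case_id] = extract_all(case, config, observer=observer)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=feature_manifest().names)
    table.index.name = "case_id"
    return table
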