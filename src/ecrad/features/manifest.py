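"""The canonical 214-feature inventory: 60 3D + 154 2D features.

The manifest is built programmatically and is the single source of truth
for feature names, ordering, family membership and dimensionality.  Every
feature table produced by the pipeline has exactly these columns, in this
order.

Family counts
-------------
3D (60): 4 shape + 6 histogram + 19 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM
2D (154): 6 histogram + 9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM
          + 10 GLGCM + 18 LoG (3 sigmas x 6 stats) + 80 Gabor (5 scales
          x 8 orientations x {MSA, MSE})

Gabor features are named ``Gabor2D_MSA-so`` / ``Gabor2D_MSE-so`` where
``s`` is the scale index (1-5, coarse to fine in frequency 0.05-0.4
cycles/pixel) and ``o`` the orientation index (1-8, theta = (o-1)*pi/8).
MSA is the mean magnitude of the complex filter response over ROI pixels;
MSE the Shannon entropy of its 16-bin magnitude histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

HISTOGRAM_STATS = ["mean", "variance", "skewness", "kurtosis", "energy", "entropy"]

GLCM_FEATURES_3D = [
    "Energy", "Contrast", "Correlation", "Homogeneity", "Entropy",
    "Dissimilarity", "Autocorrelation", "ClusterShade", "ClusterProminence",
    "ClusterTendency", "MaximumProbability", "SumAverage", "SumEntropy",
    "SumVariance", "DifferenceEntropy", "DifferenceVariance",
    "InverseDifference", "InverseVariance", "IMC1",
]
GLCM_FEATURES_2D = [
    "Energy", "Contrast", "Correlation", "Homogeneity", "Entropy",
    "Dissimilarity", "MaximumProbability", "SumAverage", "SumEntropy",
]
GLRLM_FEATURES = [
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
]
GLSZM_FEATURES = [
    "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
]
NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
GLGCM_FEATURES = [
    "SmallGradientEmphasis", "LargeGradientEmphasis", "GrayNonuniformity",
    "GradientNonuniformity", "Energy", "Correlation", "GrayEntropy",
    "GradientEntropy", "GradientMean", "GradientVariance",
]
SHAPE_FEATURES = ["volume", "size", "solidity", "eccentricity"]
LOG_SIGMAS = [1.0, 2.0, 2.5]
GABOR_N_SCALES = 5
GABOR_N_ORIENTATIONS = 8


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    family: str  # shape | histogram | texture | transform
    dimensionality: str  # "2D" | "3D"
    definition_id: str


class FeatureManifest:
    """Ordered, validated inventory of the 214 features."""

    def __init__(self, entries: list[ManifestEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in manifest")
        self.entries = entries

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def count(self, *, dimensionality: str | None = None,
              family: str | None = None) -> int:
        n = 0
        for e in self.entries:
            if dimensionality is not None and e.dimensionality != dimensionality:
                continue
            if family is not None and e.family != family:
                continue
            n += 1
        return n

    def family_of(self, name: str) -> str:
        return self._by_name()[name].family

    def _by_name(self) -> dict[str, ManifestEntry]:
        if not hasattr(self, "_index"):
            self._index = {e.name: e for e in self.entries}
        return self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "name": e.name, "family": e.family,
            "dimensionality": e.dimensionality, "definition_id": e.definition_id,
        } for e in self.entries])


def _build_entries() -> list[ManifestEntry]:
    entries: list[ManifestEntry] = []

    def add(name, family, dim, definition_id):
        entries.append(ManifestEntry(name, family, dim, definition_id))

    # --- 3D features -------------------------------------------------
    for f in SHAPE_FEATURES:
        add(f"Shape3D_{f}", "shape", "3D", f"shape.{f}")
    for s in HISTOGRAM_STATS:
        add(f"Histogram3D_{s}", "histogram", "3D", f"histogram.{s}")
    for f in GLCM_FEATURES_3D:
        add(f"GLCM3D_{f}", "texture", "3D", f"glcm.{f}")
    for f in GLRLM_FEATURES:
        add(f"GLRLM3D_{f}", "texture", "3D", f"glrlm.{f}")
    for f in GLSZM_FEATURES:
        add(f"GLSZM3D_{f}", "texture", "3D", f"glszm.{f}")
    for f in NGTDM_FEATURES:
        add(f"NGTDM3D_{f}", "texture", "3D", f"ngtdm.{f}")

    # --- 2D features -------------------------------------------------
    for s in HISTOGRAM_STATS:
        add(f"Histogram2D_{s}", "histogram", "2D", f"histogram.{s}")
    for f in GLCM_FEATURES_2D:
        add(f"GLCM2D_{f}", "texture", "2D", f"glcm.{f}")
    for f in GLRLM_FEATURES:
        add(f"GLRLM2D_{f}", "texture", "2D", f"glrlm.{f}")
    for f in GLSZM_FEATURES:
        add(f"GLSZM2D_{f}", "texture", "2D", f"glszm.{f}")
    for f in NGTDM_FEATURES:
        add(f"NGTDM2D_{f}", "texture", "2D", f"ngtdm.{f}")
    for f in GLGCM_FEATURES:
        add(f"GLGCM2D_{f}", "texture", "2D", f"glgcm.{f}")
    for sigma in LOG_SIGMAS:
        for s in HISTOGRAM_STATS:
            add(f"LoG2D_sigma{sigma:g}_{s}", "texture", "2D",
                f"log.sigma{sigma:g}.{s}")
    for stat in ("MSA", "MSE"):
        for s in range(1, GABOR_N_SCALES + 1):
            for o in range(1, GABOR_N_ORIENTATIONS + 1):
                add(f"Gabor2D_{stat}-{s}{o}", "transform", "2D",
                    f"gabor.{stat}.s{s}.o{o}")
    return entries


@lru_cache(maxsize=1)
def feature_manifest() -> FeatureManifest:
    """The canonical manifest (cached singleton)."""
    m = FeatureManifest(_build_entries())
    assert len(m) == 214
    assert m.count(dimensionality="3D") == 60
    assert m.count(dimensionality="2D") == 154
    return m
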