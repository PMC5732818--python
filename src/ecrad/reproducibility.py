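"""Inter-observer reproducibility: per-feature ICC filtering.

Each feature is computed twice per case, once per radiologist contour, and
the two columns are compared with a two-way mixed-effects, single-measure,
absolute-agreement intraclass correlation (the common choice for two fixed
raters).  Features with ICC below the threshold (default 0.8) are dropped
before any statistical screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features.manifest import feature_manifest

DEFAULT_ICC_THRESHOLD = 0.8


@dataclass
class IccResult:
    feature_name: str
    icc: float
    reproducible: bool


def icc_two_way(ratings: np.ndarray) -> float:
    """Two-way mixed, single-measure, absolute-agreement ICC for n x 2 data.

    Computed from the standard mean-square decomposition of the two-way
    layout (cases x raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-case, MSC the between-rater and MSE the residual
    mean square.  A table with zero total variance is perfect trivial
    agreement and returns 1.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an n_cases x n_raters matrix")
    n, k = ratings.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 cases")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings contain non-finite values")
    grand = ratings.mean()
    if np.allclose(ratings, grand):
        return 1.0
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((ratings - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def filter_reproducible(
    table_obs1: pd.DataFrame,
    table_obs2: pd.DataFrame,
    threshold: float = DEFAULT_ICC_THRESHOLD,
) -> tuple[list[str], list[IccResult]]:
    """Keep features whose inter-observer ICC is >= threshold.

    Both tables must share case ids; cases present in only one table are
    excluded from the comparison (single-contour cases).  Feature order of
    ``table_obs1`` (the manifest order) is preserved in the kept list.
    """
    common = table_obs1.index.intersection(table_obs2.index)
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 cases with both contours, got {len(common)}")
    if list(table_obs1.columns) != list(table_obs2.columns):
        raise ValueError("observer tables have mismatched feature columns")
    a = table_obs1.loc[common]
    b = table_obs2.loc[common]
    results = []
    kept = []
    for name in table_obs1.columns:
        icc = icc_two_way(np.column_stack([a[name].values, b[name].values]))
        ok = icc >= threshold
        results.append(IccResult(name, icc, ok))
        if ok:
            kept.append(name)
    return kept, results


def icc_report(results: list[IccResult],
               threshold: float = DEFAULT_ICC_THRESHOLD) -> pd.DataFrame:
    """Per-feature ICC table with family annotation."""
    manifest = feature_manifest()
    rows = []
    for r in results:
        try:
            family = manifest.family_of(r.feature_name)
        except KeyError:
            family = "unknown"
        rows.append({"feature": r.feature_name, "family": family,
                     "icc": r.icc, "kept": r.reproducible})
    return pd.DataFrame(rows)


def family_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Counts of failing features per family (the reproducibility summary)."""
    grp = report.groupby("family", sort=False)
    return pd.DataFrame({
        "n_features": grp.size(),
        "n_failed": grp.apply(lambda g: int((~g["kept"]).sum()),
                              include_groups=False),
    }).reset_index()
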