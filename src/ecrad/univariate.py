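"""Univariate screening: Kruskal–Wallis tests, ROC analysis, DeLong test.

Screening runs three contrasts — responders (CR+PR) vs nonresponders (SD),
SD vs PR, and SD vs CR — with a rank-based Kruskal–Wallis test per feature
(two-group Kruskal–Wallis is the tie-corrected rank-sum test).  Features
significant in the main contrast get a full ROC work-up: Mann–Whitney AUC,
DeLong standard error, normal-approximation 95% CI, and the Youden-optimal
cut-off with its sensitivity and specificity.  Raw p-values are reported;
no multiple-testing correction is applied.

The positive class throughout is the *nonresponder* group, so a cut-off
side ``>`` reads "values above the cut-off indicate a nonresponder".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_LEVEL = 0.05
MAIN_CONTRAST = "responders-vs-nonresponders"
CONTRASTS = (MAIN_CONTRAST, "SD-vs-PR", "SD-vs-CR")


@dataclass
class RocResult:
    feature_name: str
    auc: float
    se: float
    ci95: tuple[float, float]
    cutoff: float
    side: str  # ">" or "<="
    sensitivity: float  # percent
    specificity: float  # percent
    p_value: float


@dataclass
class ScreeningResult:
    pvalues: pd.DataFrame  # features x contrasts
    roc: list[RocResult] = field(default_factory=list)

    @property
    def significant(self) -> list[str]:
        p = self.pvalues[MAIN_CONTRAST]
        return list(p.index[p < SIGNIFICANCE_LEVEL])


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    All-identical values give (0, 1) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("each group must be nonempty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# DeLong machinery

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive), V01 (per negative), and the AUC."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for one score vector."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    v10, v01, auc = _placements(pos, neg)
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return auc, s10 / len(pos) + s01 / len(neg)


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Paired DeLong test of AUC(a) = AUC(b) on the same cases.

    Returns (z, two-sided p).  Zero variance of the AUC difference (e.g.
    identical or rank-equivalent predictors) returns (0, 1).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("score vectors and labels must share one case set")
    pos_a, neg_a = scores_a[labels], scores_a[~labels]
    pos_b, neg_b = scores_b[labels], scores_b[~labels]
    if len(pos_a) == 0 or len(neg_a) == 0:
        raise ValueError("both classes must be present")
    v10 = np.column_stack([_placements(pos_a, neg_a)[0],
                           _placements(pos_b, neg_b)[0]])
    v01 = np.column_stack([_placements(pos_a, neg_a)[1],
                           _placements(pos_b, neg_b)[1]])
    auc_a = v10[:, 0].mean()
    auc_b = v10[:, 1].mean()
    m, n = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10.T) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01.T) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# ROC with Youden cut-off

def roc_analysis(scores: np.ndarray, labels: np.ndarray,
                 feature_name: str = "") -> RocResult:
    """Mann–Whitney AUC with DeLong SE, 95% CI and Youden-optimal cut-off.

    ``labels`` marks the positive class (nonresponders in the screening
    stage).  The AUC is oriented to be >= 0.5; the orientation is recorded
    as the cut-off side: ">" when positives score high, "<=" when they
    score low (positive predicted for score <= cut-off).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc_raw, _ = delong_variance(scores, labels)
    side = ">" if auc_raw >= 0.5 else "<="
    oriented = scores if side == ">" else -scores
    auc, var = delong_variance(oriented, labels)
    se = float(np.sqrt(var))
    ci = (float(np.clip(auc - 1.96 * se, 0, 1)),
          float(np.clip(auc + 1.96 * se, 0, 1)))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    # Youden cut-off over midpoints of adjacent observed (oriented) scores
    uniq = np.unique(oriented)
    cuts = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else uniq
    best = None
    for c in cuts:
        pred = oriented > c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or \
                (abs(j - best[0]) <= 1e-12 and sens > best[1]):
            best = (j, sens, spec, c)
    _, sens, spec, cut = best
    cutoff = cut if side == ">" else -cut
    return RocResult(feature_name=feature_name, auc=auc, se=se, ci95=ci,
                     cutoff=float(cutoff), side=side,
                     sensitivity=float(100 * sens),
                     specificity=float(100 * spec), p_value=p)


# ---------------------------------------------------------------------------
# screening driver

def _contrast_groups(labels: pd.Series, contrast: str) -> pd.Series | None:
    """Group assignment per case for one contrast, or None if a class is empty."""
    if contrast == MAIN_CONTRAST:
        grp = labels.map(lambda l: "R" if l in ("CR", "PR") else "NR")
    elif contrast == "SD-vs-PR":
        grp = labels[labels.isin(["SD", "PR"])]
    elif contrast == "SD-vs-CR":
        grp = labels[labels.isin(["SD", "CR"])]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if grp.nunique() < 2:
        return None
    return grp


def univariate_screen(table: pd.DataFrame, labels: pd.Series) -> ScreeningResult:
    """Run the three contrasts and the ROC work-up of main-contrast hits.

    ``table`` is a kept-feature table (rows = cases); ``labels`` maps case
    id to CR/PR/SD/PD.  Results are sorted by main-contrast p-value.
    """
    labels = labels.loc[table.index]
    pvals = {}
    for contrast in CONTRASTS:
        grp = _contrast_groups(labels, contrast)
        if grp is None:
            import warnings
            warnings.warn(f"contrast {contrast} skipped: a class is empty",
                          stacklevel=2)
            pvals[contrast] = pd.Series(np.nan, index=table.columns)
            continue
        sub = table.loc[grp.index]
        pvals[contrast] = pd.Series(
            {f: kruskal_wallis(sub[f].values, grp.values)[1]
             for f in table.columns})
    pframe = pd.DataFrame(pvals).sort_values(MAIN_CONTRAST)
    result = ScreeningResult(pvalues=pframe)
    nonresp = ~labels.map(lambda l: l in ("CR", "PR")).astype(bool)
    for feature in result.significant:
        result.roc.append(
            roc_analysis(table[feature].values, nonresp.values, feature))
    return result


def roc_table(rocs: list[RocResult]) -> pd.DataFrame:
    """ROC results in reporting layout (one row per feature)."""
    return pd.DataFrame([{
        "feature": r.feature_name, "p_value": r.p_value, "se": r.se,
        "ci95_low": r.ci95[0], "ci95_high": r.ci95[1], "auc": r.auc,
        "cutoff": r.cutoff, "side": r.side,
        "sensitivity_pct": r.sensitivity, "specificity_pct": r.specificity,
    } for r in rocs])
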