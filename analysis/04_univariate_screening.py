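"""Screen reproducible features for response discrimination.

Kruskal–Wallis tests on three contrasts (responders vs nonresponders,
SD vs PR, SD vs CR) plus ROC analysis — AUC, DeLong SE, 95% CI, Youden
cut-off with sensitivity/specificity — for every feature significant in
the main contrast, and a DeLong comparison of the two best AUCs.
"""

import sys
from pathlib import Path

import pandas as pd

from ecrad.univariate import (
    MAIN_CONTRAST, delong_test, roc_table, univariate_screen,
)

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    try:
        table = pd.read_csv(SCRATCH / "features_kept.csv", index_col="case_id")
    except FileNotFoundError:
        print("run analysis/03_reproducibility_filter.py first", file=sys.stderr)
        return 1
    labels = pd.read_csv(SCRATCH / "cohort" / "cohort.csv").set_index(
        "case_id")["label"]
    res = univariate_screen(table, labels)
    RESULTS.mkdir(exist_ok=True)
    res.pvalues.head(25).round(6).to_csv(RESULTS / "screening_top_pvalues.csv")
    res.pvalues.to_csv(SCRATCH / "screening_pvalues.csv")
    roc = roc_table(res.roc)
    roc.round(4).head(25).to_csv(RESULTS / "screening_roc.csv", index=False)
    roc.to_csv(SCRATCH / "screening_roc_full.csv", index=False)

    print(f"{len(res.significant)} features significant in the main contrast "
          f"(Kruskal-Wallis p < 0.05)")
    if len(res.roc) >= 2:
        top = roc.sort_values("auc", ascending=False).head(5)
        print("strongest discriminators:")
        print(top[["feature", "auc", "cutoff", "side", "sensitivity_pct",
                   "specificity_pct"]].to_string(index=False))
        a, b = top.iloc[0]["feature"], top.iloc[1]["feature"]
        nonresp = ~labels.loc[table.index].isin(["CR", "PR"])
        z, p = delong_test(table[a].values, table[b].values, nonresp.values)
        print(f"DeLong {a} vs {b}: z = {z:.3f}, p = {p:.3f}")


if __name__ == "__main__":
    sys.exit(main())
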