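"""Filter features by inter-observer reproducibility (ICC >= 0.8).

Compares the two observers' feature tables with a two-way mixed,
single-measure, absolute-agreement ICC per feature and keeps those at or
above 0.8, summarizing the failures by family.
"""

import sys
from pathlib import Path

import pandas as pd

from ecrad.reproducibility import family_summary, filter_reproducible, icc_report

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    try:
        t1 = pd.read_csv(SCRATCH / "features_obs1.csv", index_col="case_id")
        t2 = pd.read_csv(SCRATCH / "features_obs2.csv", index_col="case_id")
    except FileNotFoundError:
        print("run analysis/02_extract_features.py first", file=sys.stderr)
        return 1
    kept, results = filter_reproducible(t1, t2, threshold=0.8)
    rep = icc_report(results)
    rep.to_csv(SCRATCH / "icc_report.csv", index=False)
    summary = family_summary(rep)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "icc_family_summary.csv", index=False)
    t1[kept].to_csv(SCRATCH / "features_kept.csv")
    print(f"{len(kept)}/{len(results)} features reproducible (ICC >= 0.8)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
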