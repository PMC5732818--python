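"""Generate the synthetic study cohort.

Builds the default 49-case cohort (33 responders: 17 CR + 16 PR; 16
nonresponders: 16 SD) of ellipsoidal tumors with class-conditional texture
(responders: symmetric intensity histograms, 4 mm correlation length;
nonresponders: right-skewed, 8 mm), writes it as NIfTI volumes + masks
under scratch/cohort/, and records a per-case summary table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ecrad.synthetic_cohort import SyntheticCohortSpec, generate_cohort, write_cohort

SEED = 0
COHORT_DIR = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    spec = SyntheticCohortSpec(seed=SEED)
    cases = generate_cohort(spec)
    write_cohort(cases, COHORT_DIR, spec=spec)

    rows = []
    for c in cases:
        x = c.volume[c.mask_primary]
        z = (x - x.mean()) / x.std()
        rows.append({
            "case_id": c.case_id, "label": c.label, "responder": c.responder,
            "n_voxels": int(c.mask_primary.sum()),
            "mean_intensity": round(float(x.mean()), 2),
            "intensity_skewness": round(float((z ** 3).mean()), 4),
        })
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "cohort_summary.csv", index=False)

    by_class = table.groupby("responder")["intensity_skewness"].mean()
    print(f"wrote {len(cases)} cases to {COHORT_DIR}")
    print(table["label"].value_counts().to_string())
    print(f"mean in-mask skewness: responders {by_class[True]:.3f}, "
          f"nonresponders {by_class[False]:.3f} "
          "(nonresponders right-skewed, as planted)")


if __name__ == "__main__":
    sys.exit(main())
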