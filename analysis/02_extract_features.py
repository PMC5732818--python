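"""Extract the 214-feature tables for both observers.

Each case is resampled to 1 mm isotropic voxels, its ROI quantized to 16
gray levels, and the full inventory (60 3D + 154 2D features) computed on
the 3D ROI and on the largest axial section — once per observer contour.
Feature tables go to scratch/ (they feed the next stages); the feature
inventory itself is recorded under results/.
"""

import sys
from pathlib import Path

from ecrad.features.extract import extract_table
from ecrad.features.manifest import feature_manifest
from ecrad.pipeline import read_case_directory

COHORT_DIR = Path("scratch/cohort")
SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    if not COHORT_DIR.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    cases = read_case_directory(COHORT_DIR)
    manifest = feature_manifest()
    RESULTS.mkdir(exist_ok=True)
    manifest.to_frame().to_csv(RESULTS / "feature_inventory.csv", index=False)
    for observer in (1, 2):
        table = extract_table(cases, observer=observer)
        out = SCRATCH / f"features_obs{observer}.csv"
        table.to_csv(out)
        print(f"observer {observer}: {table.shape[0]} cases x "
              f"{table.shape[1]} features -> {out}")
    print(f"inventory: {len(manifest)} features "
          f"({manifest.count(dimensionality='3D')} 3D, "
          f"{manifest.count(dimensionality='2D')} 2D)")


if __name__ == "__main__":
    sys.exit(main())
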