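"""Build and validate the SVM and ANN response classifiers.

Splits the cohort 37 train / 12 test (5 test nonresponders), runs
wrapper-based backward feature elimination per algorithm on the training
split, reports 10-fold cross-validated metrics (support-weighted TP/FP
rate, precision, accuracy, F-measure, MCC, AUC), compares the two models
with McNemar's test on the out-of-fold predictions, and evaluates the
untouched hold-out split.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from ecrad.models import (
    ModelConfig, cross_validate, evaluate_holdout, mcnemar_test,
    stratified_split, train_classifier, wrapper_select,
)

SCRATCH = Path("scratch")
RESULTS = Path("results")
SEED = 0
N_CANDIDATES = 12


def main() -> None:
    try:
        feats = pd.read_csv(SCRATCH / "features_kept.csv", index_col="case_id")
        pvals = pd.read_csv(SCRATCH / "screening_pvalues.csv",
                            index_col=0)
    except FileNotFoundError:
        print("run analysis/04_univariate_screening.py first", file=sys.stderr)
        return 1
    cohort = pd.read_csv(SCRATCH / "cohort" / "cohort.csv").set_index("case_id")
    nonresp = ~cohort["responder"].astype(bool)

    train_ids, test_ids = stratified_split(nonresp, n_test=12, seed=SEED,
                                           n_test_positive=5)
    y_train = nonresp.loc[train_ids].astype(int).values
    y_test = nonresp.loc[test_ids].astype(int).values
    candidates = [f for f in pvals.index if f in feats.columns][:N_CANDIDATES]
    print(f"training {len(train_ids)} cases ({y_train.sum()} nonresponders), "
          f"testing {len(test_ids)} ({y_test.sum()} nonresponders); "
          f"{len(candidates)} wrapper candidates")

    report, rows, oof = {}, [], {}
    for i, algo in enumerate(("svm", "ann")):
        cfg = ModelConfig(algorithm=algo, n_folds=10, seed=SEED + i)
        selected = wrapper_select(feats.loc[train_ids, candidates], y_train, cfg)
        cv, oof[algo] = cross_validate(feats.loc[train_ids, selected],
                                       y_train, cfg)
        model = train_classifier(feats.loc[train_ids, selected], y_train, cfg)
        hold, cm = evaluate_holdout(model, feats.loc[test_ids, selected], y_test)
        report[algo] = {"selected_features": selected, "cv": cv.as_dict(),
                        "holdout": hold.as_dict(),
                        "holdout_confusion": cm.tolist()}
        rows += [{"algorithm": algo, "split": "train_cv10", **cv.as_dict()},
                 {"algorithm": algo, "split": "holdout", **hold.as_dict()}]
        print(f"{algo}: selected {selected}")
        print(f"{algo}: CV accuracy {cv.accuracy:.3f}, MCC {cv.mcc:.3f}, "
              f"AUC {cv.auc:.3f}; hold-out accuracy {hold.accuracy:.3f}")

    b, c, p = mcnemar_test(oof["svm"]["y_pred"].values,
                           oof["ann"]["y_pred"].values, y_train)
    report["mcnemar"] = {"b": b, "c": c, "p_value": p}
    print(f"McNemar SVM vs ANN on out-of-fold predictions: "
          f"b={b}, c={c}, p = {p:.3f}")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).round(4).to_csv(RESULTS / "model_metrics.csv",
                                       index=False)
    (RESULTS / "model_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    sys.exit(main())
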