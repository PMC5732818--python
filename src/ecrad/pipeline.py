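"""End-to-end orchestration: cohort → features → ICC → screen → models.

``run_pipeline`` executes the whole analysis from one config, persisting
every intermediate table under the output directory so each reported
number can be recomputed from disk:

    cohort.csv                cohort labels and split assignment
    features_obs1.csv         214-feature table, observer-1 contours
    features_obs2.csv         214-feature table, observer-2 contours
    icc_report.csv            per-feature ICC and keep/drop flag
    screening_pvalues.csv     Kruskal–Wallis p per contrast
    screening_roc.csv         ROC work-up of main-contrast hits
    model_report.json         selection, CV/hold-out metrics, McNemar

All randomness flows from one global seed expanded into per-stage child
seeds (recorded in the report), so a rerun with the same config reproduces
byte-identical feature tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features.extract import ExtractionConfig, extract_table
from .features.manifest import feature_manifest
from .models import (
    ModelConfig, cross_validate, evaluate_holdout, mcnemar_test,
    stratified_split, train_classifier, wrapper_select,
)
from .reproducibility import family_summary, filter_reproducible, icc_report
from .synthetic_cohort import (
    PatientCase, SyntheticCohortSpec, VALID_LABELS, generate_cohort,
)
from .univariate import MAIN_CONTRAST, roc_table, univariate_screen

log = logging.getLogger("ecrad")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config driving the full analysis."""

    cohort: SyntheticCohortSpec | str | Path = field(
        default_factory=SyntheticCohortSpec)  # spec, or a case directory
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    icc_threshold: float = 0.8
    n_test: int = 12
    n_test_nonresponders: int = 5
    n_wrapper_candidates: int = 12
    n_folds: int = 10
    algorithms: tuple[str, ...] = ("svm", "ann")
    out_dir: str | Path = "ecrad_run"
    seed: int = 0


def read_case_directory(path: str | Path) -> list[PatientCase]:
    """Load a cohort written as NIfTI volumes/masks plus ``cohort.csv``."""
    import nibabel as nib

    path = Path(path)
    table_path = path / "cohort.csv"
    if not table_path.exists():
        raise PipelineStageError("ingest", f"missing {table_path}")
    table = pd.read_csv(table_path)
    cases = []
    for row in table.itertuples():
        cid = str(row.case_id)
        if row.label not in VALID_LABELS:
            raise PipelineStageError(
                "ingest", f"case {cid}: unknown label {row.label!r}")
        vol_img = nib.load(path / f"{cid}_volume.nii.gz")
        spacing = tuple(float(z) for z in vol_img.header.get_zooms()[:3])
        volume = np.asarray(vol_img.dataobj, dtype=float)
        mask1 = np.asarray(
            nib.load(path / f"{cid}_mask1.nii.gz").dataobj) > 0
        mask2_path = path / f"{cid}_mask2.nii.gz"
        mask2 = (np.asarray(nib.load(mask2_path).dataobj) > 0
                 if mask2_path.exists() else None)
        if mask1.shape != volume.shape:
            raise PipelineStageError("ingest", f"case {cid}: mask shape mismatch")
        cases.append(PatientCase(case_id=cid, volume=volume, spacing=spacing,
                                 mask_primary=mask1, mask_secondary=mask2,
                                 label=str(row.label)))
    return cases


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    report: dict = {"seed": config.seed, "stage_seeds": {
        "cohort": seeds[0], "split": seeds[1], "svm": seeds[2], "ann": seeds[3]}}

    # ---- cohort ------------------------------------------------------
    if isinstance(config.cohort, (str, Path)):
        cases = read_case_directory(config.cohort)
    else:
        cases = generate_cohort(config.cohort)
    labels = pd.Series({c.case_id: c.label for c in cases}, name="label")
    responder = labels.map(lambda l: l in ("CR", "PR"))
    report["cohort"] = {
        "n_cases": len(cases),
        "n_responders": int(responder.sum()),
        "n_nonresponders": int((~responder).sum()),
    }
    log.info("cohort: %s", report["cohort"])

    # ---- features (both observers) -----------------------------------
    try:
        t1 = extract_table(cases, config.extraction, observer=1)
        t2 = extract_table(cases, config.extraction, observer=2)
    except Exception as exc:
        raise PipelineStageError("extract", str(exc)) from exc
    t1.to_csv(out / "features_obs1.csv")
    t2.to_csv(out / "features_obs2.csv")
    manifest = feature_manifest()
    report["features"] = {
        "n_features": len(manifest),
        "n_3d": manifest.count(dimensionality="3D"),
        "n_2d": manifest.count(dimensionality="2D"),
        "n_cases_obs1": len(t1), "n_cases_obs2": len(t2),
    }

    # ---- ICC filter --------------------------------------------------
    kept, icc_results = filter_reproducible(t1, t2, config.icc_threshold)
    rep = icc_report(icc_results, config.icc_threshold)
    rep.to_csv(out / "icc_report.csv", index=False)
    report["reproducibility"] = {
        "threshold": config.icc_threshold,
        "n_kept": len(kept),
        "n_dropped": len(manifest) - len(kept),
        "n_single_contour_cases": len(t1) - len(t1.index.intersection(t2.index)),
        "by_family": family_summary(rep).to_dict(orient="records"),
    }
    if not kept:
        report["status"] = ("no feature passed the ICC threshold "
                            f"{config.icc_threshold}; downstream stages skipped")
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
        return report

    features = t1[kept]

    # ---- univariate screening (full cohort, as in the source design) --
    screen = univariate_screen(features, labels)
    screen.pvalues.to_csv(out / "screening_pvalues.csv")
    roc_frame = roc_table(screen.roc)
    roc_frame.to_csv(out / "screening_roc.csv", index=False)
    report["screening"] = {
        "n_significant_main": len(screen.significant),
        "significant": screen.significant,
        "contrast_sizes": {
            MAIN_CONTRAST: [int(responder.sum()), int((~responder).sum())],
            "SD-vs-PR": [int((labels == "SD").sum()), int((labels == "PR").sum())],
            "SD-vs-CR": [int((labels == "SD").sum()), int((labels == "CR").sum())],
        },
    }

    # ---- split + models ----------------------------------------------
    nonresp = ~responder
    train_ids, test_ids = stratified_split(
        nonresp, n_test=config.n_test, seed=seeds[1],
        n_test_positive=config.n_test_nonresponders)
    y_train = nonresp.loc[train_ids].astype(int).values
    y_test = nonresp.loc[test_ids].astype(int).values
    report["split"] = {
        "n_train": len(train_ids), "n_test": len(test_ids),
        "train_nonresponders": int(y_train.sum()),
        "test_nonresponders": int(y_test.sum()),
    }

    # wrapper candidates: best main-contrast features among kept ones
    ranked = [f for f in screen.pvalues.index if f in set(kept)]
    candidates = ranked[:config.n_wrapper_candidates]
    report["wrapper_candidates"] = candidates

    oof = {}
    report["models"] = {}
    for algo, algo_seed in zip(("svm", "ann"), (seeds[2], seeds[3])):
        if algo not in config.algorithms:
            continue
        mc = ModelConfig(algorithm=algo, n_folds=config.n_folds, seed=algo_seed)
        selected = wrapper_select(features.loc[train_ids, candidates],
                                  y_train, mc)
        cv_metrics, oof_frame = cross_validate(
            features.loc[train_ids, selected], y_train, mc)
        oof[algo] = oof_frame
        model = train_classifier(features.loc[train_ids, selected], y_train, mc)
        test_metrics, cm = evaluate_holdout(
            model, features.loc[test_ids, selected], y_test)
        report["models"][algo] = {
            "selected_features": selected,
            "cv": cv_metrics.as_dict(),
            "holdout": test_metrics.as_dict(),
            "holdout_confusion": cm.tolist(),
        }
        log.info("%s: CV acc %.3f, hold-out acc %.3f", algo,
                 cv_metrics.accuracy, test_metrics.accuracy)

    if len(oof) == 2:
        b, c, p = mcnemar_test(oof["svm"]["y_pred"].values,
                               oof["ann"]["y_pred"].values, y_train)
        report["mcnemar"] = {"b_svm_only_correct": b,
                             "c_ann_only_correct": c, "p_value": p}

    splits = pd.Series("train", index=labels.index)
    splits.loc[test_ids] = "test"
    cohort_frame = pd.DataFrame({"case_id": labels.index, "label": labels.values,
                                 "responder": responder.values,
                                 "split": splits.values})
    cohort_frame.to_csv(out / "cohort.csv", index=False)
    report["status"] = "ok"
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
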