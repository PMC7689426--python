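#!/usr/bin/env python
"""Ten-fold cross-validated MACCE classification with the five-model suite.

Runs MLP, J48, NaiveBayes, RandomForest and SMO on the selected features,
pools held-out predictions over stratified folds, replicates the CV over 10
fold seeds for confidence intervals, tests each feature between outcome
groups (Mann-Whitney), and compares AUCs against the best model
(Hanley-McNeil z).
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from cmrtexture.evaluate import feature_mann_whitney
from cmrtexture.pipeline import compare_aucs, evaluate_classifiers, stage_seed

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    table = pd.read_csv(RUN_DIR / "cohort_table.csv", index_col=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = evaluate_classifiers(table, seed=stage_seed(SEED, "evaluate"))
        comparisons = compare_aucs(results)
        mw = feature_mann_whitney(table)

    rows = []
    for name, entry in results.items():
        for orient, m in entry["metrics"].items():
            for metric, row in m["replicates"].iterrows():
                rows.append({"classifier": name, "positive_class": orient,
                             "metric": metric, "mean": round(row["mean"], 4),
                             "ci_lo": round(row["ci_lo"], 4),
                             "ci_hi": round(row["ci_hi"], 4)})
    pd.DataFrame(rows).to_csv(RESULTS / "metrics.csv", index=False)
    comparisons.round(4).to_csv(RESULTS / "auc_comparisons.csv", index=False)
    mw.round(6).to_csv(RESULTS / "mann_whitney.csv")

    wide = (pd.DataFrame(rows).query("positive_class == 1")
            .pivot(index="classifier", columns="metric", values="mean"))
    print(wide[["sensitivity", "specificity", "precision", "recall",
                "f_measure", "roc_auc", "prc_area"]].round(3).to_string())
    if len(comparisons):
        print("\nAUC comparisons (Hanley-McNeil):")
        print(comparisons.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
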