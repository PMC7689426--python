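#!/usr/bin/env python
"""Reliability- and redundancy-based dimension reduction.

Appends the clinical covariates (age, sex, BMI) to the texture tables,
drops every feature whose inter- or intra-reader ICC(2,1) is <= 0.6, prunes
survivors with pairwise Pearson |r| > 0.8 (reliability-ranked greedy sweep),
and reports how many survivors derive from each sequence.
"""

import warnings
from pathlib import Path

import pandas as pd

from cmrtexture.pipeline import attach_covariates, select_features
from cmrtexture.reliability import kept_features

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"


def main():
    tables = {r: pd.read_csv(RUN_DIR / f"features_{r}.csv", index_col=0)
              for r in ("reader1_read1", "reader1_read2", "reader2_read1")}
    meta = pd.read_csv(RUN_DIR / "cohort" / "cohort.csv").set_index("subject_id")

    class _Sub:
        def __init__(self, sid, row):
            self.subject_id = sid
            self.age, self.sex, self.bmi = row["age"], int(row["sex"]), row["bmi"]

    subjects = [_Sub(sid, row) for sid, row in meta.iterrows()]
    tables = attach_covariates(tables, subjects)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = select_features(tables, icc_threshold=0.6, r_threshold=0.8)
    report.round(4).to_csv(RESULTS / "reliability_report.csv")

    kept = kept_features(report)
    n_icc = int((report["verdict"] == "drop_icc").sum())
    n_red = int((report["verdict"] == "drop_redundant").sum())
    t2w = [f for f in kept if f.startswith("T2w.")]
    lge = [f for f in kept if f.startswith("LGE.")]
    print(f"{len(report)} features in; dropped {n_icc} for ICC <= 0.6, "
          f"{n_red} as redundant (|r| > 0.8); kept {len(kept)}")
    print(f"kept by origin: {len(t2w)} T2w, {len(lge)} LGE, "
          f"{len(kept) - len(t2w) - len(lge)} clinical")
    pd.Series(kept, name="feature").to_csv(RESULTS / "kept_features.csv", index=False)

    table = tables["reader1_read1"][kept].copy()
    table["MACCE"] = meta["MACCE"].reindex(table.index).to_numpy()
    table.to_csv(RUN_DIR / "cohort_table.csv")


if __name__ == "__main__":
    main()
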