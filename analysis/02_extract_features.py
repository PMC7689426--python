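#!/usr/bin/env python
"""Extract the texture panel for every subject, sequence and ROI reading.

Reads the simulated cohort from disk through the same I/O layer a DICOM
study would use (resampling to the 0.390625 mm grid, rasterizing each
reader's polygon), evaluates the 282-descriptor panel per sequence, and
writes one feature table per reading under scratch/ (they are wide).
"""

import warnings
from pathlib import Path

from cmrtexture.pipeline import (drop_missing_features, extract_cohort_tables,
                                 load_cohort_from_dir, _DiskSubject)
from cmrtexture.registry import default_registry, save_registry

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"


def main():
    subjects = [_DiskSubject(d) for d in load_cohort_from_dir(RUN_DIR / "cohort")]
    registry = default_registry()
    save_registry(registry, RUN_DIR / "registry.txt")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = drop_missing_features(extract_cohort_tables(subjects, registry))
    for reading, t in tables.items():
        t.to_csv(RUN_DIR / f"features_{reading}.csv")
        print(f"{reading}: {t.shape[0]} subjects x {t.shape[1]} features")


if __name__ == "__main__":
    main()
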