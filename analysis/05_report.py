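#!/usr/bin/env python
"""Assemble the human-readable run summary from the analysis outputs."""

import shutil
from pathlib import Path

from cmrtexture.pipeline import write_report

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"


def main():
    # write_report reads from one directory; stage the small tables there
    for name in ("reliability_report.csv", "metrics.csv", "auc_comparisons.csv"):
        src = RESULTS / name
        if src.exists():
            shutil.copy(src, RUN_DIR / name)
    text = write_report(RUN_DIR)
    (RESULTS / "summary.md").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
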