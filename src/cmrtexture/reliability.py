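"""Reliability- and redundancy-based dimension reduction.

Features are measured three times per subject (reader 1 twice, two weeks
apart, and reader 2 once).  Inter-reader agreement is the ICC between reader
1's first read and reader 2's read; intra-reader agreement between reader
1's two reads.  The ICC variant is the two-way random-effects, absolute
agreement, single-measure ICC(2,1): with n subjects and k ratings,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

from the row (subject), column (rating) and error mean squares of the
two-way ANOVA.  A feature is dropped when min(inter, intra) <= 0.6 — both
agreements must be adequate.  Survivors are then pruned greedily in order of
descending mean ICC: a feature is kept iff its absolute Pearson correlation
with every already-kept feature is <= 0.8 (strictly greater correlations
mark redundancy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ICC_THRESHOLD = 0.6
R_THRESHOLD = 0.8

__all__ = [
    "ICC_THRESHOLD", "R_THRESHOLD", "ReaderMeasurements",
    "compute_icc", "landis_koch_band", "reliability_filter", "redundancy_prune",
]


@dataclass(frozen=True)
class ReaderMeasurements:
    """Aligned per-feature subject tables for the three ROI readings."""

    reader1_read1: pd.DataFrame   # subjects x features
    reader1_read2: pd.DataFrame
    reader2_read1: pd.DataFrame

    def __post_init__(self):
        a, b, c = self.reader1_read1, self.reader1_read2, self.reader2_read1
        if not (a.shape == b.shape == c.shape):
            raise ValueError("reading tables must be congruent")
        if len(a) < 3:
            raise ValueError("at least 3 subjects required")
        if not (list(a.columns) == list(b.columns) == list(c.columns)):
            raise ValueError("reading tables must share feature columns")
        for t in (a, b, c):
            if t.isna().any().any():
                raise ValueError("readings contain missing values; drop those "
                                 "features upstream")


def compute_icc(x, y) -> float:
    """ICC(2,1) between two aligned subject-vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ICC inputs must be finite")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or ss_rows + ss_err == 0:
        warnings.warn("zero between-subject variance: ICC defined as 0")
        return 0.0
    return float((msr - mse) / denom)


def landis_koch_band(icc: float) -> str:
    """Agreement band: substantial (0.60, 0.80], excellent (0.80, 1.00]."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc > 0.80:
        return "excellent"
    if icc > 0.60:
        return "substantial"
    return "poor/moderate"


def reliability_filter(measurements: ReaderMeasurements,
                       threshold: float = ICC_THRESHOLD) -> pd.DataFrame:
    """Per-feature ICC report with keep / drop_icc verdicts.

    Columns: icc_inter, icc_intra, band_inter, band_intra, verdict, partner
    (partner is filled later by :func:`redundancy_prune`).
    """
    a = measurements.reader1_read1
    rows = []
    for feat in a.columns:
        inter = compute_icc(a[feat], measurements.reader2_read1[feat])
        intra = compute_icc(a[feat], measurements.reader1_read2[feat])
        verdict = "drop_icc" if min(inter, intra) <= threshold else "keep"
        rows.append({
            "feature": feat,
            "icc_inter": inter,
            "icc_intra": intra,
            "band_inter": landis_koch_band(inter),
            "band_intra": landis_koch_band(intra),
            "verdict": verdict,
            "partner": "",
        })
    return pd.DataFrame(rows).set_index("feature")


def redundancy_prune(table: pd.DataFrame, report: pd.DataFrame,
                     r_threshold: float = R_THRESHOLD) -> pd.DataFrame:
    """Greedy correlation pruning of the ICC-surviving features.

    ``table`` holds one reading (subjects x features) used for the Pearson
    correlations.  Survivors are visited in order of descending
    mean(icc_inter, icc_intra), ties broken by the incoming column order; a
    feature is kept iff |r| <= r_threshold against every already-kept
    feature, and a dropped feature records its first offending partner.
    Zero-variance features are dropped with a warning (correlation
    undefined).
    """
    report = report.copy()
    survivors = [f for f in table.columns if report.at[f, "verdict"] == "keep"]
    mean_icc = {f: (report.at[f, "icc_inter"] + report.at[f, "icc_intra"]) / 2
                for f in survivors}
    order = {f: i for i, f in enumerate(table.columns)}
    survivors.sort(key=lambda f: (-mean_icc[f], order[f]))

    kept: list[str] = []
    for feat in survivors:
        col = table[feat].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"zero-variance feature {feat!r} dropped (correlation undefined)")
            report.at[feat, "verdict"] = "drop_redundant"
            report.at[feat, "partner"] = "<zero-variance>"
            continue
        offender = None
        for other in kept:
            r = np.corrcoef(col, table[other].to_numpy(dtype=float))[0, 1]
            # strict >, with an epsilon guard so a mathematically exact
            # boundary correlation is not tipped over by float round-off
            if abs(r) > r_threshold + 1e-12:
                offender = other
                break
        if offender is None:
            kept.append(feat)
        else:
            report.at[feat, "verdict"] = "drop_redundant"
            report.at[feat, "partner"] = offender
    return report


def kept_features(report: pd.DataFrame) -> list[str]:
    return [f for f in report.index if report.at[f, "verdict"] == "keep"]
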