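"""End-to-end orchestration: simulate -> preprocess -> extract -> select -> evaluate.

The pipeline can run purely in memory (`run_pipeline`) from a synthetic
cohort spec, or file-based (`run_all`) against a run directory, reading
images and ROIs back through the same I/O layer a real study would use.
All randomness flows from a single master seed through deterministic
per-stage child seeds; rerunning with the same manifest reproduces
byte-identical feature tables and metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import READINGS, SyntheticCohortSpec, generate_cohort, write_cohort
from .engine import extract_vector
from .evaluate import (CLASSIFIER_NAMES, ClassifierSpec, estimate_auc_correlation,
                       feature_mann_whitney, hanley_mcneil, metrics_with_ci,
                       pooled_metrics, run_crossval)
from .images import (DEFAULT_SPACING_MM, GrayImage, load_roi_json, rasterize_roi,
                     read_image, resample_to_spacing, rescale_polygon)
from .registry import default_registry, save_registry
from .reliability import (ICC_THRESHOLD, R_THRESHOLD, ReaderMeasurements,
                          kept_features, redundancy_prune, reliability_filter)

log = logging.getLogger("cmrtexture")

SEQUENCES = ("T2w", "LGE")


@dataclass
class RunConfig:
    seed: int = 0
    target_spacing: float = DEFAULT_SPACING_MM
    icc_threshold: float = ICC_THRESHOLD
    r_threshold: float = R_THRESHOLD
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    k_folds: int = 10
    n_ci_seeds: int = 10
    include_covariates: bool = True
    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def __post_init__(self):
        if not (0.0 <= self.icc_threshold <= 1.0 and 0.0 <= self.r_threshold <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.target_spacing <= 0:
            raise ValueError("target spacing must be positive")
        for c in self.classifiers:
            ClassifierSpec(c)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "cohort" in d:
            c = d["cohort"]
            for key in ("age_clip", "bmi_clip", "inner_radius", "outer_radius",
                        "ellipticity"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = SyntheticCohortSpec(**c)
        d["classifiers"] = tuple(d.get("classifiers", CLASSIFIER_NAMES))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# Extraction

def extract_reading_table(pairs: dict[str, tuple[GrayImage, object]],
                          registry=None) -> pd.Series:
    """Feature row for one subject reading: columns '<sequence>.<name>'."""
    values = {}
    for seq, (img, poly) in pairs.items():
        mask = rasterize_roi(poly, img.shape)
        vec = extract_vector(img, mask, registry, seq)
        for name, val in vec.values.items():
            values[f"{seq}.{name}"] = np.nan if val is None else val
    return pd.Series(values)


def extract_cohort_tables(subjects, registry=None,
                          target_spacing: float = DEFAULT_SPACING_MM
                          ) -> dict[str, pd.DataFrame]:
    """Per-reading feature tables (subjects x '<sequence>.<name>' columns)."""
    if registry is None:
        registry = default_registry()
    tables = {reading: {} for reading in READINGS}
    for s in subjects:
        imgs = {"T2w": resample_to_spacing(s.t2w, target_spacing),
                "LGE": resample_to_spacing(s.lge, target_spacing)}
        for reading in READINGS:
            poly = s.rois[reading]
            tables[reading][s.subject_id] = extract_reading_table(
                {seq: (imgs[seq], poly) for seq in SEQUENCES}, registry)
    return {r: pd.DataFrame(v).T for r, v in tables.items()}


def drop_missing_features(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Drop any feature missing for at least one subject in any reading."""
    bad = set()
    for t in tables.values():
        bad |= set(t.columns[t.isna().any()])
    if bad:
        log.info("dropping %d features with missing values", len(bad))
    return {r: t.drop(columns=sorted(bad & set(t.columns))) for r, t in tables.items()}


def attach_covariates(tables: dict[str, pd.DataFrame], subjects
                      ) -> dict[str, pd.DataFrame]:
    """Append age/sex/BMI; identical across readings, like any other feature."""
    cov = pd.DataFrame({
        "age": {s.subject_id: s.age for s in subjects},
        "sex": {s.subject_id: float(s.sex) for s in subjects},
        "bmi": {s.subject_id: s.bmi for s in subjects},
    })
    return {r: pd.concat([t, cov.loc[t.index]], axis=1) for r, t in tables.items()}


# ---------------------------------------------------------------------------
# Selection + evaluation

def select_features(tables: dict[str, pd.DataFrame], icc_threshold: float,
                    r_threshold: float) -> pd.DataFrame:
    meas = ReaderMeasurements(tables["reader1_read1"], tables["reader1_read2"],
                              tables["reader2_read1"])
    report = reliability_filter(meas, icc_threshold)
    report = redundancy_prune(tables["reader1_read1"], report, r_threshold)
    for feat, row in report.iterrows():
        if row["verdict"] != "keep":
            log.debug("dropped %s (%s, partner=%s)", feat, row["verdict"], row["partner"])
    return report


def build_cohort_table(tables: dict[str, pd.DataFrame], report: pd.DataFrame,
                       subjects) -> pd.DataFrame:
    kept = kept_features(report)
    table = tables["reader1_read1"][kept].copy()
    table["MACCE"] = [s.macce for s in subjects]
    return table


def evaluate_classifiers(table: pd.DataFrame, classifiers=CLASSIFIER_NAMES,
                         k: int = 10, seed: int = 0, n_ci_seeds: int = 10
                         ) -> dict[str, dict]:
    """Metrics (both orientations, with CIs) and pooled scores per classifier."""
    rng = np.random.default_rng(seed)
    ci_seeds = [int(v) for v in rng.integers(0, 2 ** 31, n_ci_seeds)]
    out = {}
    for name in classifiers:
        spec = ClassifierSpec(name)
        replicates = [run_crossval(table, spec, k=k, seed=s) for s in ci_seeds]
        res = replicates[0]
        entry = {"cv": res, "metrics": {}}
        for orient in (1, 0):
            entry["metrics"][orient] = {
                "pooled": pooled_metrics(res, orient),
                "replicates": metrics_with_ci(replicates, orient),
            }
        out[name] = entry
    return out


def compare_aucs(results: dict[str, dict]) -> pd.DataFrame:
    """Hanley-McNeil z-tests between the top-AUC classifier and each other."""
    aucs = {n: r["metrics"][1]["pooled"]["roc_auc"] for n, r in results.items()}
    if len(aucs) < 2:
        return pd.DataFrame(columns=["best", "other", "auc_best", "auc_other",
                                     "r_hm", "z", "p"])
    best = max(aucs, key=aucs.get)
    y = results[best]["cv"].y_true
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    rows = []
    for other, auc in aucs.items():
        if other == best:
            continue
        r_hm = estimate_auc_correlation(results[best]["cv"].scores,
                                        results[other]["cv"].scores, y)
        cmp_ = hanley_mcneil(aucs[best], n_pos, n_neg, auc, r_hm)
        rows.append({"best": best, "other": other, "auc_best": aucs[best],
                     "auc_other": auc, "r_hm": r_hm, "z": cmp_.z, "p": cmp_.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-pipeline drivers

@dataclass
class PipelineResult:
    subjects: list
    tables: dict[str, pd.DataFrame]
    report: pd.DataFrame
    cohort_table: pd.DataFrame
    classifier_results: dict[str, dict]
    auc_comparisons: pd.DataFrame
    mw_tests: pd.DataFrame | None = None

    @property
    def kept(self) -> list[str]:
        return kept_features(self.report)


def run_pipeline(config: RunConfig, subjects=None, registry=None,
                 classifiers=None) -> PipelineResult:
    """In-memory end-to-end run on a (generated) synthetic cohort."""
    if subjects is None:
        subjects = generate_cohort(config.cohort, stage_seed(config.seed, "simulate"))
    tables = extract_cohort_tables(subjects, registry, config.target_spacing)
    tables = drop_missing_features(tables)
    if config.include_covariates:
        tables = attach_covariates(tables, subjects)
    report = select_features(tables, config.icc_threshold, config.r_threshold)
    cohort_table = build_cohort_table(tables, report, subjects)
    if not cohort_table.columns.drop("MACCE").size:
        log.warning("no features survive selection; skipping evaluation")
        return PipelineResult(subjects, tables, report, cohort_table, {},
                              pd.DataFrame())
    clf = classifiers if classifiers is not None else config.classifiers
    results = evaluate_classifiers(cohort_table, clf, config.k_folds,
                                   stage_seed(config.seed, "evaluate"),
                                   config.n_ci_seeds)
    comparisons = compare_aucs(results)
    mw = feature_mann_whitney(cohort_table)
    return PipelineResult(subjects, tables, report, cohort_table, results,
                          comparisons, mw)


def load_cohort_from_dir(run_dir, target_spacing: float = DEFAULT_SPACING_MM):
    """Read a simulated (or real, identically laid out) cohort from disk."""
    run_dir = Path(run_dir)
    meta = pd.read_csv(run_dir / "cohort.csv").set_index("subject_id")
    loaded = []
    for sid, row in meta.iterrows():
        imgs = {}
        polys = {}
        for seq in SEQUENCES:
            native = read_image(run_dir / f"{sid}_{seq}.pgm")
            imgs[seq] = resample_to_spacing(native, target_spacing)
            scale = (native.spacing_row, native.spacing_col)
        for reading in READINGS:
            poly = load_roi_json(run_dir / f"{sid}_roi_{reading}.json")
            polys[reading] = rescale_polygon(poly, scale[0], scale[1], target_spacing)
        loaded.append({"subject_id": sid, "images": imgs, "rois": polys,
                       "age": float(row["age"]), "sex": int(row["sex"]),
                       "bmi": float(row["bmi"]), "macce": int(row["MACCE"])})
    return loaded


class _DiskSubject:
    """Adapter giving disk-loaded cohorts the SyntheticSubject surface."""

    def __init__(self, d):
        self.subject_id = d["subject_id"]
        self.t2w = d["images"]["T2w"]
        self.lge = d["images"]["LGE"]
        self.rois = d["rois"]
        self.age, self.sex, self.bmi, self.macce = d["age"], d["sex"], d["bmi"], d["macce"]


def run_all(config: RunConfig, run_dir) -> Path:
    """File-based pipeline: simulate, write, read back, extract, select, evaluate."""
    run_dir = Path(run_dir)
    cohort_dir = run_dir / "cohort"
    sim_seed = stage_seed(config.seed, "simulate")
    subjects = generate_cohort(config.cohort, sim_seed)
    write_cohort(subjects, cohort_dir, config.cohort, sim_seed)

    loaded = [_DiskSubject(d) for d in load_cohort_from_dir(cohort_dir,
                                                            config.target_spacing)]
    registry = default_registry()
    save_registry(registry, run_dir / "registry.txt")
    result = run_pipeline(config, subjects=loaded, registry=registry)

    for reading, t in result.tables.items():
        t.to_csv(run_dir / f"features_{reading}.csv")
    result.report.to_csv(run_dir / "reliability_report.csv")
    save_registry([d for d in registry
                   if any(f"{s}.{d.name}" in result.kept for s in SEQUENCES)],
                  run_dir / "kept_registry.txt")
    result.cohort_table.to_csv(run_dir / "cohort_table.csv")
    if result.classifier_results:
        metrics_rows = []
        for name, entry in result.classifier_results.items():
            for orient, m in entry["metrics"].items():
                rep = m["replicates"]
                for metric, row in rep.iterrows():
                    metrics_rows.append({"classifier": name, "positive_class": orient,
                                         "metric": metric, "mean": row["mean"],
                                         "ci_lo": row["ci_lo"], "ci_hi": row["ci_hi"]})
        pd.DataFrame(metrics_rows).to_csv(run_dir / "metrics.csv", index=False)
        result.auc_comparisons.to_csv(run_dir / "auc_comparisons.csv", index=False)
        if result.mw_tests is not None:
            result.mw_tests.to_csv(run_dir / "mann_whitney.csv")
    manifest = {"config": json.loads(config.to_json()),
                "config_hash": config.config_hash(),
                "stage_seeds": {s: stage_seed(config.seed, s)
                                for s in ("simulate", "evaluate")}}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def write_report(run_dir) -> str:
    """Human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    if not (run_dir / "reliability_report.csv").exists():
        raise FileNotFoundError("incomplete run: no reliability report")
    report = pd.read_csv(run_dir / "reliability_report.csv", index_col=0)
    kept = report[report["verdict"] == "keep"]
    lines = ["# Pipeline run summary", "",
             f"Features evaluated: {len(report)}",
             f"Dropped for ICC <= threshold: {(report['verdict'] == 'drop_icc').sum()}",
             f"Dropped as redundant: {(report['verdict'] == 'drop_redundant').sum()}",
             f"Kept: {len(kept)}", "", "## Kept features (ICC bands)"]
    for feat, row in kept.iterrows():
        lines.append(f"- {feat}: inter {row['icc_inter']:.2f} ({row['band_inter']}), "
                     f"intra {row['icc_intra']:.2f} ({row['band_intra']})")
    metrics_path = run_dir / "metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path)
        lines += ["", "## Classifier metrics (positive class = MACCE 1 / 0)"]
        for name in metrics["classifier"].unique():
            for orient in (1, 0):
                sub = metrics[(metrics["classifier"] == name)
                              & (metrics["positive_class"] == orient)]
                sub = sub.set_index("metric")
                row = ", ".join(
                    f"{m} {sub.at[m, 'mean']:.3f} "
                    f"[{sub.at[m, 'ci_lo']:.3f}-{sub.at[m, 'ci_hi']:.3f}]"
                    for m in ("sensitivity", "specificity", "roc_auc", "prc_area"))
                lines.append(f"- {name} (positive={orient}): {row}")
            auc = metrics[(metrics["classifier"] == name)
                          & (metrics["positive_class"] == 1)].set_index("metric")
            lo, hi = auc.at["roc_auc", "ci_lo"], auc.at["roc_auc", "ci_hi"]
            if lo <= 0.5 <= hi:
                lines.append(f"  note: {name} AUC CI covers 0.5 (no discrimination)")
        cmp_path = run_dir / "auc_comparisons.csv"
        if cmp_path.exists():
            cmps = pd.read_csv(cmp_path)
            if len(cmps):
                lines += ["", "## Hanley-McNeil AUC comparisons (best vs rest)"]
                for _, r in cmps.iterrows():
                    lines.append(f"- {r['best']} (AUC {r['auc_best']:.3f}) vs "
                                 f"{r['other']} (AUC {r['auc_other']:.3f}): "
                                 f"z = {r['z']:.2f}, p = {r['p']:.4f}")
    else:
        lines += ["", "No features survived selection; evaluation skipped."]
    text = "\n".join(lines) + "\n"
    (run_dir / "summary.md").write_text(text)
    return text
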