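"""Cross-validated MACCE classification and the accompanying statistics.

Five classifiers mirror a classic WEKA-style suite:
a single-hidden-layer multilayer perceptron with floor((p + c)/2) hidden
units, learning rate 0.3 and momentum 0.2 (ANN-MLP); a pruned C4.5-style
decision tree (J48); Gaussian naive Bayes; a random forest of bagged trees
with feature subsampling; and a linear-kernel support-vector classifier
(SMO).  Evaluation is stratified ten-fold cross-validation with the
held-out predictions pooled over folds before metrics are computed — with
six events among 58 subjects, unstratified folds regularly contain no event
and pooling keeps every metric defined.  Confidence intervals come from
replicating the whole cross-validation over independent fold seeds.

AUC comparisons use the Hanley & McNeil (1982/1983) closed-form standard
error and z-test; per-feature group differences use the Mann-Whitney U test
(exact by enumeration for small samples, tie- and continuity-corrected
normal approximation otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = ("ANN-MLP", "J48", "NaiveBayes", "RandomForest", "SMO")


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameter mapping of one classifier in the suite."""

    name: str

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"choose from {CLASSIFIER_NAMES}")

    def build(self, n_features: int, seed: int):
        if self.name == "ANN-MLP":
            hidden = max(1, (n_features + 2) // 2)
            return MLPClassifier(hidden_layer_sizes=(hidden,), solver="sgd",
                                 learning_rate_init=0.3, momentum=0.2,
                                 max_iter=500, random_state=seed)
        if self.name == "J48":
            return DecisionTreeClassifier(criterion="entropy", ccp_alpha=0.01,
                                          random_state=seed)
        if self.name == "NaiveBayes":
            return GaussianNB()
        if self.name == "RandomForest":
            return RandomForestClassifier(n_estimators=100, max_features="sqrt",
                                          random_state=seed)
        if self.name == "SMO":
            return SVC(kernel="linear", probability=False, random_state=seed)
        raise AssertionError(self.name)


@dataclass
class CVResult:
    y_true: np.ndarray            # pooled over folds, original subject order
    scores: np.ndarray            # P(MACCE=1) or decision value, pooled
    y_pred: np.ndarray            # hard labels, pooled
    fold_of: np.ndarray           # fold index per subject
    seed: int
    spec: ClassifierSpec


def _scores_of(model, x) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, list(model.classes_).index(1)]
    d = model.decision_function(x)
    return d if model.classes_[1] == 1 else -d


def run_crossval(table: pd.DataFrame, spec: ClassifierSpec, k: int = 10,
                 seed: int = 0, label_col: str = "MACCE") -> CVResult:
    """Seeded stratified k-fold CV; held-out scores pooled over folds."""
    y = table[label_col].to_numpy(dtype=int)
    x = table.drop(columns=[label_col]).to_numpy(dtype=float)
    n = len(y)
    if k > n:
        raise ValueError("more folds than subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    y_true = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    y_pred = np.empty(n, dtype=int)
    fold_of = np.empty(n, dtype=int)
    sub_seed = seed
    for _ in range(10):  # refold on a degenerate split (single-class training)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=sub_seed % (2 ** 31))
        folds = list(skf.split(x, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
        warnings.warn("fold with single-class training set; refolding with new sub-seed")
        sub_seed += 104729
    for fi, (tr, te) in enumerate(folds):
        scaler = StandardScaler().fit(x[tr])
        model = spec.build(x.shape[1], seed)
        model.fit(scaler.transform(x[tr]), y[tr])
        xt = scaler.transform(x[te])
        y_true[te] = y[te]
        scores[te] = _scores_of(model, xt)
        y_pred[te] = model.predict(xt)
        fold_of[te] = fi
    return CVResult(y_true, scores, y_pred, fold_of, seed, spec)


# ---------------------------------------------------------------------------
# Metrics

def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank (midrank-tie) AUC — the Mann-Whitney U / (n1 n2) identity."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n1 = int((y_true == 1).sum())
    n0 = int((y_true == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    r1 = ranks[y_true == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def prc_area(y_true: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import average_precision_score
    return float(average_precision_score(y_true, scores))


def pooled_metrics(result: CVResult, positive_class: int = 1) -> dict[str, float]:
    """Sensitivity, specificity, precision, recall, F-measure, ROC-AUC, PRC area.

    ``positive_class`` selects which MACCE label counts as positive; both
    orientations satisfy the sensitivity/specificity exchange.
    """
    y = (result.y_true == positive_class).astype(int)
    pred = (result.y_pred == positive_class).astype(int)
    s = result.scores if positive_class == 1 else -result.scores
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    if tp + fn == 0:
        raise ValueError("no subjects of the chosen positive class; "
                         "use the other orientation")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens > 0 else 0.0
    return {
        "TP": tp, "FN": fn, "TN": tn, "FP": fp,
        "sensitivity": sens, "specificity": spec,
        "precision": prec, "recall": sens, "f_measure": f1,
        "roc_auc": roc_auc(y, s), "prc_area": prc_area(y, s),
    }


METRIC_KEYS = ("sensitivity", "specificity", "precision", "recall",
               "f_measure", "roc_auc", "prc_area")


def replicate_metrics(table: pd.DataFrame, spec: ClassifierSpec, k: int = 10,
                      seeds=range(10), positive_class: int = 1) -> pd.DataFrame:
    """CV metrics replicated over fold seeds, with normal-approximation CIs.

    Returns a one-row-per-metric frame with mean, ci_lo, ci_hi over the
    replicate pooled metrics (95%, CI of the replicate mean).
    """
    results = [run_crossval(table, spec, k, s) for s in seeds]
    return metrics_with_ci(results, positive_class)


def metrics_with_ci(results: list[CVResult], positive_class: int = 1) -> pd.DataFrame:
    """Aggregate pooled metrics of replicate CV results into mean + 95% CI."""
    reps = [pooled_metrics(r, positive_class) for r in results]
    rows = []
    m = len(reps)
    for key in METRIC_KEYS:
        vals = np.array([r[key] for r in reps], dtype=float)
        mean = vals.mean()
        half = 1.96 * vals.std(ddof=1) / sqrt(m) if m > 1 else 0.0
        rows.append({"metric": key, "mean": mean,
                     "ci_lo": mean - half, "ci_hi": mean + half})
    return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# Hanley-McNeil AUC comparison

@dataclass(frozen=True)
class AucComparison:
    a1: float
    a2: float
    se1: float
    se2: float
    r_hm: float
    z: float
    p: float


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of a ROC AUC (Hanley & McNeil 1982)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return sqrt(max(var, 0.0))


def hanley_mcneil(a1: float, n_pos: int, n_neg: int, a2: float,
                  r_hm: float = 0.0) -> AucComparison:
    """z-test for the difference of two AUCs measured on the same subjects."""
    if not -1.0 <= r_hm <= 1.0:
        raise ValueError("r_hm must lie in [-1, 1]")
    se1 = hanley_mcneil_se(a1, n_pos, n_neg)
    se2 = hanley_mcneil_se(a2, n_pos, n_neg)
    denom_sq = se1 * se1 + se2 * se2 - 2.0 * r_hm * se1 * se2
    if denom_sq <= 0:
        if a1 == a2:
            return AucComparison(a1, a2, se1, se2, r_hm, 0.0, 1.0)
        raise ValueError("comparison undefined: zero standard error of the difference")
    z = (a1 - a2) / sqrt(denom_sq)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
    return AucComparison(a1, a2, se1, se2, r_hm, z, p)


def estimate_auc_correlation(scores_a: np.ndarray, scores_b: np.ndarray,
                             y_true: np.ndarray) -> float:
    """Estimate the Hanley-McNeil r term from paired classifier scores.

    The average of the within-positive and within-negative Pearson
    correlations of the two score vectors, a standard plug-in for the 1983
    table lookup.
    """
    y_true = np.asarray(y_true)
    rs = []
    for cls in (0, 1):
        sa = np.asarray(scores_a)[y_true == cls]
        sb = np.asarray(scores_b)[y_true == cls]
        if len(sa) >= 2 and np.std(sa) > 0 and np.std(sb) > 0:
            rs.append(np.corrcoef(sa, sb)[0, 1])
    return float(np.clip(np.mean(rs), -1.0, 1.0)) if rs else 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass(frozen=True)
class TestResult:
    u: float
    p: float
    method: str


def mann_whitney(group_a, group_b, exact_limit: int = 12) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U comes from midrank-tied rank sums.  For n1 + n2 <= ``exact_limit`` the
    p-value is exact, by enumerating every assignment of the pooled values
    to the two groups; otherwise a normal approximation with tie correction
    and a 0.5 continuity correction is used.  Identical pooled values give
    p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups: p = 1")
        return TestResult(u=n1 * n2 / 2.0, p=1.0, method="degenerate")

    def u_of(idx_a: np.ndarray) -> float:
        ranks = rankdata(pooled)
        r1 = ranks[idx_a].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u = u_of(np.arange(n1))
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        dev = abs(u - mu)
        hits = total = 0
        ranks = rankdata(pooled)
        for idx in combinations(range(n1 + n2), n1):
            r1 = ranks[list(idx)].sum()
            u_i = r1 - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_i - mu) >= dev - 1e-12:
                hits += 1
        assert total == comb(n1 + n2, n1)
        return TestResult(u=u, p=hits / total, method="exact")

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # pragma: no cover - fully tied data handled above
        return TestResult(u=u, p=1.0, method="normal")
    z = (abs(u - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return TestResult(u=u, p=min(p, 1.0), method="normal")


def feature_mann_whitney(table: pd.DataFrame, label_col: str = "MACCE") -> pd.DataFrame:
    """Per-feature Mann-Whitney comparison between outcome groups."""
    y = table[label_col].to_numpy(dtype=int)
    rows = []
    for feat in table.columns:
        if feat == label_col:
            continue
        vals = table[feat].to_numpy(dtype=float)
        res = mann_whitney(vals[y == 1], vals[y == 0])
        rows.append({"feature": feat, "U": res.u, "p": res.p, "method": res.method})
    return pd.DataFrame(rows).set_index("feature")
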