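"""Gut-microbiome alpha diversity and obesity classifiers.

Alpha diversity is computed at the finest taxonomic rank available:
observed richness, Shannon entropy H = -sum p_i ln p_i (nats) and the Chao1
estimator S_obs + n1^2/(2 n2) (bias-corrected S_obs + n1(n1-1)/(2(n2+1))
when no doubletons exist, where the classical form is undefined). For
modeling, the taxon table is shifted by 1, log_e-transformed and z-scored
per taxon, projected onto the leading principal components, and fed to a
five-fold iteration scheme of random-forest classifiers distinguishing the
normal from the obese class (of measured BMI or of an omics-inferred BMI),
with hyperparameters chosen by internal cross-validation and one hold-out
prediction per participant. Overall ROC/AUC is computed from the pooled
hold-out probabilities and compared across classifiers with the unpaired
DeLong test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV

from .stats_core import TestResult

__all__ = [
    "alpha_diversity",
    "diversity_transform",
    "taxon_pca_features",
    "ClassifierResult",
    "fit_obesity_classifier",
    "pooled_roc",
    "delong_unpaired_test",
]


def _shannon(c: np.ndarray) -> float:
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def _chao1(c: np.ndarray) -> float:
    s_obs = int((c > 0).sum())
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    if n2 == 0:
        return s_obs + n1 * (n1 - 1) / 2.0  # bias-corrected, n2 -> n2 + 1
    return s_obs + n1**2 / (2.0 * n2)


def alpha_diversity(counts, metric: str = "shannon"):
    """Per-sample alpha diversity from taxon counts.

    ``counts`` is a single count vector or a samples x taxa DataFrame;
    metric is 'observed', 'shannon' (nats) or 'chao1'.
    """
    funcs = {"observed": lambda c: float((c > 0).sum()),
             "shannon": _shannon, "chao1": _chao1}
    if metric not in funcs:
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(counts, pd.DataFrame):
        values = counts.to_numpy(dtype=float)
        if np.any(values.sum(axis=1) <= 0):
            raise ValueError("all-zero sample")
        return pd.Series([funcs[metric](row) for row in values],
                         index=counts.index, name=metric)
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("all-zero sample")
    return funcs[metric](c)


def diversity_transform(values, metric: str) -> np.ndarray:
    """Variance-stabilize then z-score an alpha-diversity vector.

    Observed richness and Chao1 get a square-root transform; Shannon gets a
    square transform.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("diversity values must be non-negative")
    if metric in ("observed", "chao1"):
        t = np.sqrt(v)
    elif metric == "shannon":
        t = v**2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sd = t.std(ddof=0)
    if sd == 0:
        raise ValueError("constant diversity vector")
    out = (t - t.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=metric)
    return out


def taxon_pca_features(table, n_components: int = 50):
    """Project preprocessed taxon counts onto principal components.

    Counts are shifted by 1, log_e-transformed and z-scored per taxon
    (constant taxa are left centered at 0), then reduced with PCA. Returns
    ``(scores, explained_variance_ratio)``; ``n_components`` is clipped with
    a warning when it exceeds what the table supports.
    """
    counts = table.counts if hasattr(table, "counts") else table
    if counts.shape[0] < 2:
        raise ValueError("need more than one sample")
    logged = np.log(counts.to_numpy(dtype=float) + 1.0)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (logged - mean) / sd_safe
    limit = min(counts.shape[0], counts.shape[1])
    if n_components > limit:
        warnings.warn(f"n_components clipped from {n_components} to {limit}",
                      stacklevel=2)
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    cols = [f"pc{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=counts.index, columns=cols),
            pca.explained_variance_ratio_)


@dataclass
class ClassifierResult:
    """Hold-out predictions and per-fold metrics of an obesity classifier."""

    frame: pd.DataFrame        # label, probability, prediction, fold
    fold_metrics: pd.DataFrame  # auc, average_precision, sensitivity, specificity
    positive_label: str = "obese"


def fit_obesity_classifier(features: pd.DataFrame, class_labels: pd.Series,
                           k: int = 5, seed: int = 0,
                           grid: dict | None = None,
                           internal_cv: int = 5,
                           folds=None) -> ClassifierResult:
    """k-fold iteration scheme of random-forest obesity classifiers.

    ``class_labels`` must contain exactly {'normal', 'obese'} (the
    intermediate classes are excluded upstream). Folds are stratified by
    label; per fold a grid search over tree count and feature fraction is
    run with internal cross-validation on the training split, and the
    hold-out participants receive a binary vote prediction and the mean
    obese-class probability over trees. Vote ties resolve to 'normal'.
    """
    labels = class_labels.loc[features.index].astype(str)
    present = set(labels.unique())
    if present != {"normal", "obese"}:
        raise ValueError(f"need both 'normal' and 'obese' classes, got {sorted(present)}")
    y = (labels == "obese").astype(int).to_numpy()
    if folds is None:
        rng = np.random.default_rng(seed)
        folds = np.empty(len(y), dtype=int)
        for cls in (0, 1):
            loc = np.flatnonzero(y == cls)
            perm = rng.permutation(len(loc))
            folds[loc[perm]] = np.arange(len(loc)) % k
    else:
        folds = np.asarray(folds, dtype=int)
        if folds.shape != y.shape:
            raise ValueError("fold assignment length mismatch")
    grid = grid or {"n_estimators": [100, 300], "max_features": ["sqrt", 0.3]}

    prob = np.full(len(y), np.nan)
    vote = np.zeros(len(y), dtype=int)
    rows = []
    X = features.to_numpy(dtype=float)
    for f in range(k):
        tr, ho = folds != f, folds == f
        search = GridSearchCV(
            RandomForestClassifier(random_state=seed + f, n_jobs=1),
            grid, cv=internal_cv, scoring="roc_auc")
        search.fit(X[tr], y[tr])
        model = search.best_estimator_
        p = model.predict_proba(X[ho])[:, list(model.classes_).index(1)]
        votes = np.stack([t.predict(X[ho]) for t in model.estimators_])
        binary = (votes.mean(axis=0) > 0.5).astype(int)  # tie -> normal
        prob[ho], vote[ho] = p, binary
        tp = int(((binary == 1) & (y[ho] == 1)).sum())
        tn = int(((binary == 0) & (y[ho] == 0)).sum())
        fp = int(((binary == 1) & (y[ho] == 0)).sum())
        fn = int(((binary == 0) & (y[ho] == 1)).sum())
        rows.append({
            "fold": f,
            "auc": roc_auc_score(y[ho], p),
            "average_precision": average_precision_score(y[ho], p),
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        })
    frame = pd.DataFrame({
        "label": labels, "probability": prob,
        "prediction": np.where(vote == 1, "obese", "normal"),
        "fold": folds}, index=features.index)
    return ClassifierResult(frame=frame,
                            fold_metrics=pd.DataFrame(rows).set_index("fold"))


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    labels: np.ndarray
    scores: np.ndarray


def pooled_roc(result) -> RocResult:
    """Empirical ROC/AUC from all participants' hold-out probabilities."""
    if isinstance(result, ClassifierResult):
        y = (result.frame["label"] == result.positive_label).astype(int).to_numpy()
        s = result.frame["probability"].to_numpy()
    else:
        y, s = np.asarray(result[0], dtype=int), np.asarray(result[1], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(roc_auc_score(y, s)),
                     labels=y, scores=s)


def _delong_variance(y: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """(AUC, Var(AUC)) from DeLong structural components."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    # Placement values via mid-rank comparison.
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def delong_unpaired_test(roc_a: RocResult, roc_b: RocResult) -> TestResult:
    """Two-sided unpaired DeLong test comparing two AUCs.

    Appropriate when the two classifiers were evaluated on (possibly)
    different participant sets, so the covariance term of the paired test
    is dropped and the variances add.
    """
    auc_a, var_a = _delong_variance(roc_a.labels, roc_a.scores)
    auc_b, var_b = _delong_variance(roc_b.labels, roc_b.scores)
    se = np.sqrt(var_a + var_b)
    diff = auc_a - auc_b
    if se == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, estimate=0.0, ci_low=0.0, ci_high=0.0)
        raise ValueError("degenerate ROC: zero variance with differing AUCs")
    z = diff / se
    p = 2.0 * sps.norm.sf(abs(z))
    half = sps.norm.ppf(0.975) * se
    return TestResult(float(z), float(p), estimate=float(diff),
                      ci_low=float(diff - half), ci_high=float(diff + half))
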