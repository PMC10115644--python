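"""Omics-inferred BMI/WHtR: k-fold-iteration sparse-regression ensembles.

The central construct is a k-fold *iteration* scheme (default k=10): the
cohort is split once into k hold-out sets shared across omics categories and
estimators; for each fold a LASSO model is trained on the remaining k-1
sets (penalty chosen by internal cross-validation on the training set only)
against unstandardized log_e(measure); the k hold-out predictions are then
assembled so that every participant receives exactly one prediction from a
model that never saw them. Predictions are exponentiated back to measure
units (kg/m^2 for BMI) before computing the percent deviation
Delta = (pred - meas)/meas * 100.

Follow-up visits are scored with the baseline model whose hold-out set
contained the participant, and external cohorts are scored with the mean of
the k fold models, matching the hold-out discipline of the baseline design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LassoCV, LinearRegression, RidgeCV
from sklearn.model_selection import GridSearchCV

from .preprocess import homa_ir
from .stats_core import bh_adjust, out_of_sample_r2

__all__ = [
    "SplitPlan",
    "SparseEnsemble",
    "PredictionSet",
    "make_split_plan",
    "fit_cv_lasso_ensemble",
    "fit_standard_measures_model",
    "fit_alternative_estimator",
    "predict_external",
    "refit_restricted_panel",
    "predict_followup",
    "delta_measure",
    "robust_retained_set",
    "iterative_strongest_removal",
    "univariate_explained_variance",
]

RETAIN_TOL = 1e-12  # |beta| above this counts as "retained" (solver noise)


@dataclass
class SplitPlan:
    """A fixed k-fold hold-out partition shared across omics categories."""

    k: int
    fold_assignment: pd.Series  # participant -> fold in 0..k-1
    seed: int
    balance_report: pd.DataFrame | None = None

    def train_index(self, fold: int) -> pd.Index:
        return self.fold_assignment.index[self.fold_assignment != fold]

    def holdout_index(self, fold: int) -> pd.Index:
        return self.fold_assignment.index[self.fold_assignment == fold]


@dataclass
class SparseEnsemble:
    """k fitted sparse linear models plus the plan that produced them."""

    coefs: pd.DataFrame          # fold x analyte
    intercepts: pd.Series        # per fold
    penalties: pd.Series         # per fold (NaN for OLS/forest)
    panel: list
    target: str                  # e.g. "log_bmi"
    category: str
    plan: SplitPlan
    standardization: tuple | None = None   # (mean, sd) Series pair
    kind: str = "lasso"
    importances: pd.DataFrame | None = None  # random forest only
    models: list = field(default_factory=list, repr=False)

    def fold_predict_log(self, fold: int, X: pd.DataFrame) -> np.ndarray:
        if self.kind == "random_forest":
            return self.models[fold].predict(X[self.panel].to_numpy())
        beta = self.coefs.iloc[fold].to_numpy()
        return X[self.panel].to_numpy() @ beta + self.intercepts.iloc[fold]

    def to_json(self) -> str:
        if self.kind == "random_forest":
            raise ValueError("random-forest ensembles are not JSON-serializable")
        payload = {
            "kind": self.kind,
            "target": self.target,
            "category": self.category,
            "panel": list(self.panel),
            "coefs": self.coefs.to_dict(orient="list"),
            "intercepts": list(self.intercepts),
            "penalties": [None if np.isnan(v) else float(v) for v in self.penalties],
            "plan": {"k": self.plan.k, "seed": self.plan.seed,
                     "fold_assignment": self.plan.fold_assignment.to_dict()},
        }
        if self.standardization is not None:
            mean, sd = self.standardization
            payload["standardization"] = {"mean": mean.to_dict(), "sd": sd.to_dict()}
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SparseEnsemble":
        d = json.loads(text)
        assignment = pd.Series(d["plan"]["fold_assignment"])
        plan = SplitPlan(d["plan"]["k"], assignment, d["plan"]["seed"])
        coefs = pd.DataFrame(d["coefs"])[d["panel"]]
        standardization = None
        if "standardization" in d:
            standardization = (pd.Series(d["standardization"]["mean"]),
                               pd.Series(d["standardization"]["sd"]))
        return cls(
            coefs=coefs,
            intercepts=pd.Series(d["intercepts"]),
            penalties=pd.Series([np.nan if v is None else v for v in d["penalties"]]),
            panel=d["panel"], target=d["target"], category=d["category"],
            plan=plan, standardization=standardization, kind=d["kind"],
        )


@dataclass
class PredictionSet:
    """One hold-out prediction per participant, in measure units."""

    frame: pd.DataFrame      # columns: measured, predicted, delta, fold
    fold_r2: pd.Series       # out-of-sample R^2 per fold (log scale)
    pooled_r2: float
    r2_scale: str = "log"

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def make_split_plan(metadata: pd.DataFrame, k: int = 10, seed: int = 0,
                    covariates=None, stratify_by=None) -> SplitPlan:
    """Split participants into k near-equal hold-out sets.

    Assignment is uniform at random given the seed (optionally stratified by
    a categorical column); balance is then *verified* with a chi-square test
    for categorical covariates and one-way ANOVA for numeric ones, adjusted
    with Benjamini-Hochberg across the tested variables.
    """
    n = len(metadata)
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} participants, got {n}")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k
    else:
        folds = np.empty(n, dtype=int)
        offset = 0
        for _, grp in metadata.groupby(stratify_by, sort=True):
            loc = metadata.index.get_indexer(grp.index)
            perm = rng.permutation(len(loc))
            folds[loc[perm]] = (np.arange(len(loc)) + offset) % k
            offset += len(loc)
    assignment = pd.Series(folds, index=metadata.index, name="fold")

    if covariates is None:
        covariates = [c for c in ("bmi", "whtr", "sex", "age",
                                  "pc1", "pc2", "pc3", "pc4", "pc5")
                      if c in metadata.columns]
    rows = []
    for cov in covariates:
        col = metadata[cov]
        if col.dtype.kind in "OUb":
            table = pd.crosstab(col, assignment)
            stat, p = sps.chi2_contingency(table.to_numpy())[:2]
            test = "chi2"
        else:
            groups = [col[assignment == f].to_numpy() for f in range(k)]
            stat, p = sps.f_oneway(*groups)
            test = "anova"
        rows.append({"variable": cov, "test": test,
                     "statistic": float(stat), "p": float(p)})
    report = pd.DataFrame(rows)
    if len(report):
        report["p_adj"] = bh_adjust(report["p"].to_numpy())
    return SplitPlan(k=k, fold_assignment=assignment, seed=seed,
                     balance_report=report)


def _check_inputs(X: pd.DataFrame, measure: pd.Series, plan: SplitPlan):
    if X.shape[1] < 1:
        raise ValueError("need at least one analyte")
    if X.isna().to_numpy().any():
        raise ValueError("X must be complete (imputed) before fitting")
    measure = measure.loc[X.index]
    if (measure <= 0).any():
        raise ValueError("measure must be positive (log target)")
    if not set(X.index) <= set(plan.fold_assignment.index):
        raise ValueError("participants missing from the split plan")
    return measure


def _assemble(X, measure, plan, fit_fold, target, category, kind,
              standardization=None):
    """Shared hold-out assembly: fit per fold, predict that fold only."""
    log_y = np.log(measure)
    coef_rows, intercepts, penalties, models = [], [], [], []
    pred_log = pd.Series(np.nan, index=X.index)
    fold_of = plan.fold_assignment.loc[X.index]
    fold_r2 = {}
    for f in range(plan.k):
        tr = X.index[fold_of != f]
        ho = X.index[fold_of == f]
        beta, intercept, penalty, model = fit_fold(X.loc[tr], log_y.loc[tr], f)
        coef_rows.append(beta)
        intercepts.append(intercept)
        penalties.append(penalty)
        models.append(model)
        if len(ho):
            if model is not None and beta is None:
                p = model.predict(X.loc[ho].to_numpy())
            else:
                p = X.loc[ho].to_numpy() @ beta + intercept
            pred_log.loc[ho] = p
            fold_r2[f] = out_of_sample_r2(log_y.loc[ho], p)
    coefs = pd.DataFrame(
        [np.zeros(X.shape[1]) if b is None else b for b in coef_rows],
        columns=X.columns)
    ensemble = SparseEnsemble(
        coefs=coefs, intercepts=pd.Series(intercepts),
        penalties=pd.Series(penalties, dtype=float), panel=list(X.columns),
        target=target, category=category, plan=plan,
        standardization=standardization, kind=kind, models=models)
    if kind == "random_forest":
        imp = pd.DataFrame([m.feature_importances_ for m in models],
                           columns=X.columns)
        ensemble.importances = imp.div(imp.sum(axis=1), axis=0)
    predicted = np.exp(pred_log)
    frame = pd.DataFrame({
        "measured": measure,
        "predicted": predicted,
        "delta": delta_measure(predicted, measure),
        "fold": fold_of,
    })
    predictions = PredictionSet(
        frame=frame, fold_r2=pd.Series(fold_r2).sort_index(),
        pooled_r2=out_of_sample_r2(log_y, pred_log))
    return ensemble, predictions


def fit_cv_lasso_ensemble(X: pd.DataFrame, measure: pd.Series,
                          plan: SplitPlan, *, n_alphas: int = 100,
                          internal_cv: int = 10, target: str = "log_bmi",
                          category: str = "omics",
                          standardization=None):
    """Fit the k-fold LASSO ensemble on standardized analytes.

    Per fold the penalty is selected with ``internal_cv``-fold
    cross-validation (mean squared error) over ``n_alphas`` log-spaced
    penalties auto-scaled by scikit-learn from the training data, and the
    fold's hold-out participants are predicted and exponentiated back to
    measure units.
    """
    measure = _check_inputs(X, measure, plan)

    def fit_fold(X_tr, y_tr, fold):
        model = LassoCV(alphas=n_alphas, cv=internal_cv,
                        random_state=plan.seed + fold, max_iter=20_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_tr.to_numpy(), y_tr.to_numpy())
        return model.coef_, float(model.intercept_), float(model.alpha_), None

    return _assemble(X, measure, plan, fit_fold, target, category, "lasso",
                     standardization)


def fit_standard_measures_model(metadata: pd.DataFrame, plan: SplitPlan,
                                measure_col: str = "bmi"):
    """Baseline comparator: OLS on the eight standard clinical measures.

    Regressors are sex, age, triglycerides, HDL cholesterol, LDL
    cholesterol, glucose, insulin and HOMA-IR, fit with the same
    hold-out-assembly discipline and split plan as the sparse ensembles.
    """
    required = ["sex", "age", "triglycerides", "hdl", "ldl",
                "glucose", "insulin"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValueError(f"missing regressor column(s): {missing}")
    X = pd.DataFrame({
        "sex": (metadata["sex"] == "M").astype(float),
        "age": metadata["age"],
        "triglycerides": metadata["triglycerides"],
        "hdl": metadata["hdl"],
        "ldl": metadata["ldl"],
        "glucose": metadata["glucose"],
        "insulin": metadata["insulin"],
        "homa_ir": homa_ir(metadata["glucose"] / 18.0, metadata["insulin"]),
    })
    measure = _check_inputs(X, metadata[measure_col], plan)

    def fit_fold(X_tr, y_tr, fold):
        model = LinearRegression().fit(X_tr.to_numpy(), y_tr.to_numpy())
        return model.coef_, float(model.intercept_), float("nan"), None

    _, predictions = _assemble(X, measure, plan, fit_fold,
                               f"log_{measure_col}", "standard_measures", "ols")
    return predictions


def fit_alternative_estimator(X: pd.DataFrame, measure: pd.Series,
                              plan: SplitPlan, kind: str, *,
                              internal_cv: int = 10, target: str = "log_bmi",
                              category: str = "omics",
                              rf_grid: dict | None = None):
    """Same split protocol with elastic net, ridge or random forest."""
    measure = _check_inputs(X, measure, plan)
    if kind == "elastic_net":
        def fit_fold(X_tr, y_tr, fold):
            model = ElasticNetCV(l1_ratio=[0.1, 0.5, 0.9], alphas=50,
                                 cv=internal_cv, random_state=plan.seed + fold,
                                 max_iter=20_000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_tr.to_numpy(), y_tr.to_numpy())
            return model.coef_, float(model.intercept_), float(model.alpha_), None
    elif kind == "ridge":
        def fit_fold(X_tr, y_tr, fold):
            model = RidgeCV(alphas=np.logspace(-3, 3, 100), cv=internal_cv)
            model.fit(X_tr.to_numpy(), y_tr.to_numpy())
            return model.coef_, float(model.intercept_), float(model.alpha_), None
    elif kind == "random_forest":
        grid = rf_grid or {"n_estimators": [100, 300],
                           "max_features": ["sqrt", 0.3]}

        def fit_fold(X_tr, y_tr, fold):
            search = GridSearchCV(
                RandomForestRegressor(random_state=plan.seed + fold, n_jobs=1),
                grid, cv=min(internal_cv, 5),
                scoring="neg_mean_squared_error")
            search.fit(X_tr.to_numpy(), y_tr.to_numpy())
            return None, 0.0, float("nan"), search.best_estimator_
    else:
        raise ValueError(f"unknown estimator kind {kind!r}")
    return _assemble(X, measure, plan, fit_fold, target, category, kind)


def predict_external(ensemble: SparseEnsemble, X_new: pd.DataFrame) -> pd.Series:
    """Score an external cohort: mean of the k fold-model predictions,
    back-transformed to measure units. ``X_new`` must carry exactly the
    ensemble's analyte panel (standardized with the new cohort's own stats).
    """
    if set(X_new.columns) != set(ensemble.panel):
        raise ValueError("analyte panel mismatch with the fitted ensemble")
    X = X_new[ensemble.panel]
    preds = np.column_stack([
        ensemble.fold_predict_log(f, X) for f in range(ensemble.plan.k)])
    return pd.Series(np.exp(preds.mean(axis=1)), index=X_new.index,
                     name="predicted")


def refit_restricted_panel(X: pd.DataFrame, measure: pd.Series,
                           plan: SplitPlan, shared_analytes, **kwargs):
    """Full refit on a restricted analyte panel with the same split plan."""
    shared = list(shared_analytes)
    if len(shared) == 0:
        raise ValueError("empty panel restriction")
    unknown = set(shared) - set(X.columns)
    if unknown:
        raise ValueError(f"restriction includes unknown analytes: {sorted(unknown)}")
    ensemble, _ = fit_cv_lasso_ensemble(X[shared], measure, plan, **kwargs)
    return ensemble


def predict_followup(ensemble: SparseEnsemble, X_t: pd.DataFrame,
                     plan: SplitPlan | None = None) -> pd.Series:
    """Score visits with each participant's baseline hold-out fold model.

    ``X_t`` rows are indexed by participant or by (participant, day) and
    must be standardized with the baseline statistics beforehand.
    """
    plan = plan or ensemble.plan
    if isinstance(X_t.index, pd.MultiIndex):
        participants = X_t.index.get_level_values("participant")
    else:
        participants = X_t.index
    unknown = set(participants) - set(plan.fold_assignment.index)
    if unknown:
        raise ValueError(f"unknown participant(s): {sorted(unknown)[:5]}")
    folds = plan.fold_assignment.loc[participants].to_numpy()
    out = np.empty(len(X_t))
    X = X_t[ensemble.panel]
    for f in np.unique(folds):
        rows = folds == f
        out[rows] = ensemble.fold_predict_log(int(f), X.iloc[rows])
    return pd.Series(np.exp(out), index=X_t.index, name="predicted")


def delta_measure(predicted, measured):
    """Percent deviation (pred - meas)/meas * 100, in % of the measure."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if np.any(m <= 0):
        raise ValueError("measured values must be positive")
    out = (p - m) / m * 100.0
    if isinstance(predicted, pd.Series):
        return pd.Series(out, index=predicted.index, name="delta")
    return float(out) if out.ndim == 0 else out


def robust_retained_set(ensemble: SparseEnsemble) -> tuple[list, list]:
    """(intersection, union) of per-fold supports: analytes with nonzero
    coefficient in all k models, and in at least one model."""
    nonzero = ensemble.coefs.abs() > RETAIN_TOL
    intersection = [c for c in ensemble.panel if nonzero[c].all()]
    union = [c for c in ensemble.panel if nonzero[c].any()]
    return intersection, union


def iterative_strongest_removal(X: pd.DataFrame, measure: pd.Series,
                                plan: SplitPlan, n_iter: int,
                                **fit_kwargs) -> pd.DataFrame:
    """Repeatedly remove the strongest robustly-retained analyte and refit.

    Per iteration: fit the ensemble on the current panel, record its pooled
    hold-out R^2, then drop the analyte retained across all k models with
    the largest |mean beta| (lexicographic ID on exact ties). Stops early
    with a warning when no analyte is retained across all models.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    panel = list(X.columns)
    rows = []
    for it in range(n_iter):
        _, pred = None, None
        ensemble, pred = fit_cv_lasso_ensemble(X[panel], measure, plan,
                                               **fit_kwargs)
        intersection, _ = robust_retained_set(ensemble)
        if not intersection:
            warnings.warn(
                f"no analyte retained across all folds at iteration {it}; "
                "stopping early", stacklevel=2)
            break
        mean_abs = ensemble.coefs[intersection].mean().abs()
        strongest = sorted(mean_abs.index[mean_abs == mean_abs.max()])[0]
        rows.append({"iteration": it, "removed_analyte": strongest,
                     "pooled_r2": pred.pooled_r2})
        panel.remove(strongest)
    return pd.DataFrame(rows, columns=["iteration", "removed_analyte",
                                       "pooled_r2"])


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "OUb":
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                out[f"{col}[{lev}]"] = (s.astype(str) == lev).astype(float)
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=covariates.index)


def univariate_explained_variance(X: pd.DataFrame, measure: pd.Series,
                                  covariates: pd.DataFrame,
                                  inferred: dict | None = None,
                                  mode: str = "incremental") -> pd.DataFrame:
    """Per-analyte explained variance in log(measure), adjusted for covariates.

    Each analyte is regressed jointly with sex/age/ancestry covariates on
    log(measure); the default report is the incremental R^2 of
    (covariates + analyte) over covariates alone, with the analyte
    coefficient's two-sided p, BH-adjusted across the whole family. Entries
    of ``inferred`` (omics-inferred measure predictions, in measure units)
    are appended as reference rows of the same family. ``mode='total'``
    reports the full-model R^2 instead.
    """
    if mode not in ("incremental", "total"):
        raise ValueError("mode must be 'incremental' or 'total'")
    y = np.log(measure.loc[X.index].to_numpy(dtype=float))
    C = _covariate_design(covariates.loc[X.index])
    base = sm.OLS(y, sm.add_constant(C.to_numpy())).fit()
    if np.linalg.matrix_rank(sm.add_constant(C.to_numpy())) < C.shape[1] + 1:
        raise ValueError("collinear covariates")
    base_r2 = base.rsquared
    columns = {name: X[name] for name in X.columns}
    for name, pred in (inferred or {}).items():
        columns[name] = np.log(pred.loc[X.index])
    rows = []
    for name, values in columns.items():
        design = sm.add_constant(np.column_stack([C.to_numpy(), values]))
        fit = sm.OLS(y, design).fit()
        r2 = fit.rsquared - base_r2 if mode == "incremental" else fit.rsquared
        rows.append({"analyte": name, "explained_variance": float(r2),
                     "beta": float(fit.params[-1]), "p": float(fit.pvalues[-1]),
                     "is_reference": name in (inferred or {})})
    out = pd.DataFrame(rows).set_index("analyte")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
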