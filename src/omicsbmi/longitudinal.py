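"""Longitudinal trajectories with piecewise-linear time splines.

Each measured or omics-inferred BMI series is modeled on the log_e scale
with a linear mixed model: fixed effects are truncated-linear splines of
days in the program (knots at 0, 6, 12 and 18 months = 0/183/365/548 days),
sex, baseline age, ancestry PCs 1-5 and meteorological season of the visit
(Northern-hemisphere DJF/MAM/JJA/SON, winter reference); random effects are
a per-participant intercept and slope on days. A stratified variant adds a
binary misclassification stratum and its interactions with the time
splines. Estimation is REML with optimizer restarts on non-convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DEFAULT_KNOTS_DAYS",
    "spline_time_basis",
    "season_of",
    "TrajectoryModel",
    "fit_trajectory_lmm",
    "fit_strata_interaction_lmm",
    "mean_trajectory",
]

# 6/12/18 months at 30.4375 days per month, rounded to whole days.
DEFAULT_KNOTS_DAYS = (0, 183, 365, 548)
_SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
            6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def spline_time_basis(days, knots_days=DEFAULT_KNOTS_DAYS) -> pd.DataFrame:
    """Truncated-linear spline columns {t, (t-k)_+ for interior knots}.

    With the default knots this yields t, (t-183)_+ and (t-365)_+; the
    first and last knots act as boundaries and contribute no extra column.
    """
    t = np.asarray(days, dtype=float)
    if np.any(t < 0):
        raise ValueError("days must be non-negative")
    interior = list(knots_days)[1:-1]
    cols = {"t": t}
    for k in interior:
        cols[f"t_{int(k)}"] = np.clip(t - k, 0.0, None)
    idx = days.index if isinstance(days, pd.Series) else None
    return pd.DataFrame(cols, index=idx)


def season_of(dates) -> pd.Series:
    """Meteorological season (DJF/MAM/JJA/SON) of each visit date."""
    d = pd.to_datetime(pd.Series(dates))
    return d.dt.month.map(_SEASONS)


@dataclass
class TrajectoryModel:
    """A fitted trajectory LMM and the pieces needed for prediction."""

    result: object                 # statsmodels MixedLMResults
    fixed_columns: list
    spline_columns: list
    reference_row: pd.Series       # covariate means used for prediction
    knots_days: tuple
    outcome: str
    stratum_levels: tuple | None = None
    converged: bool = True


def _fixed_design(visits: pd.DataFrame, metadata: pd.DataFrame,
                  knots_days, stratum: pd.Series | None):
    part = visits["participant"]
    basis = spline_time_basis(visits["day"].to_numpy(), knots_days)
    basis.index = visits.index
    X = basis.copy()
    meta = metadata.loc[part]
    X["sex"] = (meta["sex"].to_numpy() == "M").astype(float)
    X["age"] = meta["age"].to_numpy()
    for pc in ("pc1", "pc2", "pc3", "pc4", "pc5"):
        if pc in metadata.columns:
            X[pc] = meta[pc].to_numpy()
    if "date" in visits.columns:
        season = season_of(visits["date"]).to_numpy()
    else:
        season = np.repeat("DJF", len(visits))
    for s in ("MAM", "JJA", "SON"):  # winter (DJF) is the reference
        X[f"season_{s}"] = (season == s).astype(float)
    levels = None
    if stratum is not None:
        strat = pd.Series(stratum).loc[part].astype(str).to_numpy()
        levels = tuple(sorted(np.unique(strat)))
        if len(levels) != 2:
            raise ValueError(f"stratum must be binary with both levels "
                             f"populated, got {levels}")
        ind = (strat == levels[1]).astype(float)
        X["stratum"] = ind
        for c in basis.columns:
            X[f"stratum:{c}"] = ind * basis[c].to_numpy()
    return X, list(basis.columns), levels


def fit_trajectory_lmm(visits: pd.DataFrame, metadata: pd.DataFrame,
                       outcome: str = "log_bmi",
                       knots_days=DEFAULT_KNOTS_DAYS,
                       stratum: pd.Series | None = None) -> TrajectoryModel:
    """Fit the trajectory LMM for one outcome column of ``visits``.

    ``visits`` is long-format with columns participant, day, optionally
    date, and the outcome (already log_e-transformed); ``metadata`` holds
    per-participant sex, baseline age and ancestry PCs. Random effects are
    an intercept and a slope on days/365 per participant.
    """
    if outcome not in visits.columns:
        raise ValueError(f"outcome column {outcome!r} not in visits")
    data = visits.dropna(subset=[outcome])
    multi = data.groupby("participant").size()
    if (multi >= 2).mean() < 0.1:
        raise ValueError("too few participants with repeated visits")
    X, spline_cols, levels = _fixed_design(data, metadata, knots_days, stratum)
    # Columns with no variation in the observed visit window (e.g. a
    # truncated spline term beyond the last visit, or an unobserved season)
    # are dropped; they would make the fixed-effect design singular.
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    spline_cols = [c for c in spline_cols if c not in constant]
    exog = sm.add_constant(X, has_constant="add")
    exog_re = np.column_stack([np.ones(len(data)),
                               data["day"].to_numpy() / 365.0])
    y = data[outcome].to_numpy(dtype=float)
    groups = data["participant"].to_numpy()
    model = sm.MixedLM(y, exog.to_numpy(), groups=groups, exog_re=exog_re)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=True, method=method, maxiter=200)
            except Exception:
                fit = None
                continue
            if fit.converged:
                break
    if fit is None or not np.all(np.isfinite(fit.params)):
        raise RuntimeError(f"trajectory LMM failed to converge for "
                           f"outcome {outcome!r}")
    if not fit.converged:
        warnings.warn(f"trajectory LMM for {outcome!r} did not fully "
                      "converge; estimates may be unstable", stacklevel=2)
    reference = X.drop(columns=spline_cols
                       + [c for c in X.columns if c.startswith("stratum")],
                       errors="ignore").mean()
    return TrajectoryModel(
        result=fit, fixed_columns=list(exog.columns),
        spline_columns=spline_cols, reference_row=reference,
        knots_days=tuple(knots_days), outcome=outcome,
        stratum_levels=levels, converged=bool(fit.converged))


def fit_strata_interaction_lmm(visits: pd.DataFrame, metadata: pd.DataFrame,
                               stratum: pd.Series,
                               outcome: str = "log_bmi",
                               knots_days=DEFAULT_KNOTS_DAYS) -> TrajectoryModel:
    """Trajectory LMM with a binary stratum main effect and stratum x spline
    interactions (matched vs mismatched misclassification strata)."""
    return fit_trajectory_lmm(visits, metadata, outcome=outcome,
                              knots_days=knots_days, stratum=stratum)


def mean_trajectory(model: TrajectoryModel, day_grid,
                    stratum_level: str | None = None,
                    back_transform: bool = False) -> pd.DataFrame:
    """Population-level trajectory estimate with a delta-method 95% CI.

    Non-time covariates are held at their training means; for a stratified
    model pass the stratum level to evaluate. ``back_transform`` exponentiates
    estimate and CI to measure units.
    """
    days = np.asarray(day_grid, dtype=float)
    if np.any(days < 0) :
        raise ValueError("day grid outside the modeled range")
    basis = spline_time_basis(days, model.knots_days)
    k_fe = len(model.fixed_columns)
    rows = np.zeros((len(days), k_fe))
    colpos = {c: i for i, c in enumerate(model.fixed_columns)}
    rows[:, colpos["const"]] = 1.0
    for c in basis.columns:
        if c in colpos:  # terms beyond the observed window were dropped
            rows[:, colpos[c]] = basis[c].to_numpy()
    for name, value in model.reference_row.items():
        if name in colpos:
            rows[:, colpos[name]] = value
    if model.stratum_levels is not None:
        if stratum_level is None:
            raise ValueError("stratified model needs a stratum_level")
        ind = 1.0 if stratum_level == model.stratum_levels[1] else 0.0
        rows[:, colpos["stratum"]] = ind
        for c in basis.columns:
            if f"stratum:{c}" in colpos:
                rows[:, colpos[f"stratum:{c}"]] = ind * basis[c].to_numpy()
    beta = np.asarray(model.result.fe_params)
    cov = np.asarray(model.result.cov_params())[:k_fe, :k_fe]
    est = rows @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", rows, cov, rows))
    half = sps.norm.ppf(0.975) * se
    out = pd.DataFrame({"day": days, "estimate": est,
                        "ci_low": est - half, "ci_high": est + half})
    if back_transform:
        for c in ("estimate", "ci_low", "ci_high"):
            out[c] = np.exp(out[c])
    return out
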