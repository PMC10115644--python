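"""Data cleaning, imputation, transformation and standardization.

The cleaning contract is: analytes missing in more than ``analyte_frac`` of
samples are dropped first, then samples missing more than ``sample_frac`` of
the surviving analytes are dropped. Missing values are imputed with an
iterative random-forest scheme (missForest-style); outliers beyond +/- k s.d.
are blanked; each analyte is transformed with whichever of
{identity, log, mirrored square root} minimizes absolute sample skewness and
finally z-scored, optionally against stored (baseline) statistics so that
follow-up or external data are expressed on the baseline scale.

Two preprocessing philosophies coexist: the "paper-faithful" default imputes
and standardizes the whole baseline table before any train/test split, while
callers wanting strict leak-freedom can fit the same operations within
training folds using the stored-statistics mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .stats_core import sample_skewness

__all__ = [
    "TransformSpec",
    "PanelFilterReport",
    "filter_missingness",
    "impute_iterative_forest",
    "impute_two_step",
    "trim_outliers",
    "select_skew_minimizing_transform",
    "zscore",
    "homa_ir",
    "flatten_repeated_measures",
]


@dataclass(frozen=True)
class TransformSpec:
    """A fitted, re-applicable per-analyte transformation.

    kind='log' applies log(x + shift); kind='sqrt_mirror' applies
    -sqrt(mirror_constant - x), which is increasing in x so order is
    preserved.
    """

    kind: str  # identity | log | sqrt_mirror
    shift: float = 0.0
    mirror_constant: float = 0.0

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "identity":
            return v.copy()
        if self.kind == "log":
            shifted = v + self.shift
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.log(shifted)
        if self.kind == "sqrt_mirror":
            inner = self.mirror_constant - v
            with np.errstate(invalid="ignore"):
                return -np.sqrt(np.clip(inner, 0.0, None))
        raise ValueError(f"unknown transform kind {self.kind!r}")


@dataclass(frozen=True)
class PanelFilterReport:
    """Record of the two-pass missingness filter (analytes first)."""

    dropped_analytes: tuple
    dropped_samples: tuple
    analyte_threshold: float
    sample_threshold: float


def filter_missingness(
    matrix: pd.DataFrame,
    analyte_frac: float = 0.10,
    sample_frac: float = 0.10,
) -> tuple[pd.DataFrame, PanelFilterReport]:
    """Drop analytes, then samples, with strictly-more-than-threshold missingness.

    An analyte is removed when its missing fraction across all samples exceeds
    ``analyte_frac``; afterwards a sample is removed when its missing fraction
    across the *surviving* analytes exceeds ``sample_frac``. Thresholds are
    strict (exactly 10% missing survives a 0.10 threshold).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty matrix")
    a_miss = matrix.isna().mean(axis=0)
    keep_analytes = a_miss.index[a_miss <= analyte_frac]
    if len(keep_analytes) == 0:
        raise ValueError("analyte missingness filter removed every analyte")
    trimmed = matrix[keep_analytes]
    s_miss = trimmed.isna().mean(axis=1)
    keep_samples = s_miss.index[s_miss <= sample_frac]
    if len(keep_samples) == 0:
        raise ValueError("sample missingness filter removed every sample")
    out = trimmed.loc[keep_samples]
    report = PanelFilterReport(
        dropped_analytes=tuple(c for c in matrix.columns if c not in set(keep_analytes)),
        dropped_samples=tuple(i for i in matrix.index if i not in set(keep_samples)),
        analyte_threshold=analyte_frac,
        sample_threshold=sample_frac,
    )
    return out, report


def _forest_impute(
    frame: pd.DataFrame,
    mask: pd.DataFrame,
    seed: int,
    max_iter: int,
    n_estimators: int,
    tol: float,
) -> pd.DataFrame:
    """missForest-style loop: initialize at column means, then regress each
    incomplete column on all others with a random forest until the imputed
    values stabilize or ``max_iter`` is reached."""
    work = frame.copy()
    col_means = work.mean(axis=0)
    work = work.fillna(col_means)
    incomplete = [c for c in frame.columns if mask[c].any()]
    # Most-complete columns first, as in missForest.
    incomplete.sort(key=lambda c: (int(mask[c].sum()), str(c)))
    rng = np.random.RandomState(seed % (2**31 - 1))
    prev_change = np.inf
    for _ in range(max_iter):
        before = work.copy()
        for col in incomplete:
            miss_rows = mask[col].to_numpy()
            others = [c for c in frame.columns if c != col]
            model = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.randint(0, 2**31 - 1)),
                n_jobs=1,
            )
            model.fit(work.loc[~miss_rows, others], frame.loc[~miss_rows, col])
            work.loc[miss_rows, col] = model.predict(work.loc[miss_rows, others])
        denom = float((work.to_numpy() ** 2).sum()) or 1.0
        change = float(((work - before).to_numpy() ** 2).sum()) / denom
        if change < tol or change > prev_change:
            break
        prev_change = change
    return work


def impute_iterative_forest(
    matrix: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 10,
    *,
    mode: str = "forest",
    n_estimators: int = 30,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Impute missing entries; observed entries are returned unchanged.

    mode='forest' runs the iterative random-forest scheme; mode='knn' is a
    faster k-nearest-neighbours alternative with the same contract, intended
    for large test suites.
    """
    mask = matrix.isna()
    if not mask.to_numpy().any():
        return matrix.copy()
    if mask.all(axis=0).any():
        bad = list(matrix.columns[mask.all(axis=0)])
        raise ValueError(f"all-missing column(s): {bad}")
    if mode == "knn":
        imputer = KNNImputer(n_neighbors=5)
        values = imputer.fit_transform(matrix.to_numpy(dtype=float))
        out = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    elif mode == "forest":
        out = _forest_impute(matrix, mask, seed, max_iter, n_estimators, tol)
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    out[~mask] = matrix[~mask]
    return out


def impute_two_step(
    baseline: pd.DataFrame,
    followups: list[pd.DataFrame],
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Two-step longitudinal imputation.

    Step 1 imputes the baseline table from the baseline data structure alone;
    step 2 imputes the remaining (follow-up) missingness from the overall
    stacked structure. Baseline imputed values therefore never depend on
    follow-up data.
    """
    for f in followups:
        if list(f.columns) != list(baseline.columns):
            raise ValueError("follow-up panel does not match baseline panel")
    base_done = impute_iterative_forest(baseline, seed=seed, **kwargs)
    if not followups:
        return base_done, []
    stacked = pd.concat([base_done] + list(followups), axis=0, keys=range(len(followups) + 1))
    filled = impute_iterative_forest(stacked, seed=seed + 1, **kwargs)
    out = [filled.loc[i + 1].set_axis(f.index) for i, f in enumerate(followups)]
    return base_done, out


def trim_outliers(values, k: float = 3.0):
    """Blank entries beyond mean +/- k s.d. (strict inequality).

    Mean and s.d. are computed once on the input; the rule is not
    re-iterated after trimming. Returns the same container type with trimmed
    entries set to NaN.
    """
    series = isinstance(values, pd.Series)
    v = values.to_numpy(dtype=float) if series else np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size < 2:
        raise ValueError("need >= 2 non-missing values")
    sd = obs.std(ddof=0)
    if sd == 0:
        warnings.warn("constant vector: nothing to trim", stacklevel=2)
        return values.copy() if series else v.copy()
    z = np.abs(v - obs.mean()) / sd
    out = v.copy()
    out[z > k] = np.nan
    if series:
        return pd.Series(out, index=values.index, name=values.name)
    return out


def select_skew_minimizing_transform(values) -> tuple[TransformSpec, np.ndarray]:
    """Choose the transform with smallest |skewness| among identity, log and
    mirrored square root.

    Candidates: identity; log(x - min + 1) when any value <= 0 else log(x);
    -sqrt(c - x) with c = max + 1 for left-skewed data. Ties are broken in
    the order identity > log > sqrt_mirror. NaNs pass through untouched.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if np.unique(obs).size < 3:
        raise ValueError("need >= 3 distinct non-missing values")
    lo, hi = obs.min(), obs.max()
    shift = 1.0 - lo if lo <= 0 else 0.0
    candidates = [
        TransformSpec("identity"),
        TransformSpec("log", shift=shift),
        TransformSpec("sqrt_mirror", mirror_constant=hi + 1.0),
    ]
    best = None
    for spec in candidates:  # fixed order implements the tie-break
        transformed = spec.apply(v)
        skew = abs(sample_skewness(transformed[~np.isnan(transformed)]))
        if best is None or skew < best[0] - 1e-15:
            best = (skew, spec, transformed)
    return best[1], best[2]


def zscore(data, reference_stats: tuple | None = None):
    """Standardize columns (or a vector) to mean 0, s.d. 1.

    With ``reference_stats=(mean, sd)`` the stored statistics are applied
    instead — used to put follow-up or external data on the baseline scale.
    Returns ``(standardized, (mean, sd))``.
    """
    frame = isinstance(data, pd.DataFrame)
    if frame:
        if reference_stats is None:
            mean, sd = data.mean(axis=0), data.std(axis=0, ddof=0)
        else:
            mean, sd = reference_stats
        if np.any(np.asarray(sd) == 0):
            bad = list(data.columns[np.asarray(sd) == 0]) if reference_stats is None else "reference"
            raise ValueError(f"zero-variance column(s): {bad}")
        return (data - mean) / sd, (mean, sd)
    v = np.asarray(data, dtype=float)
    if reference_stats is None:
        mean, sd = np.nanmean(v), np.nanstd(v, ddof=0)
    else:
        mean, sd = reference_stats
    if sd == 0:
        raise ValueError("zero-variance input")
    return (v - mean) / sd, (mean, sd)


def homa_ir(fasting_glucose_mmol_l, fasting_insulin_miu_l):
    """HOMA-IR = glucose (mmol/L) x insulin (mIU/L) / 22.5."""
    g = np.asarray(fasting_glucose_mmol_l, dtype=float)
    i = np.asarray(fasting_insulin_miu_l, dtype=float)
    if np.any(g < 0) or np.any(i < 0):
        raise ValueError("glucose and insulin must be non-negative")
    out = g * i / 22.5
    return float(out) if out.ndim == 0 else out


def flatten_repeated_measures(
    records: pd.DataFrame,
    value_col: str = "value",
    by: tuple = ("participant", "visit", "phenotype"),
    unit_col: str | None = None,
    unit_factors: dict | None = None,
) -> pd.DataFrame:
    """Collapse replicate measurements to one value per participant-visit-phenotype.

    Values flagged below the detection limit (non-numeric strings such as
    '<LOD' or '<5') are coded 0 before averaging. When ``unit_col`` is given,
    each value is multiplied by ``unit_factors[unit]``; an unknown unit is an
    error.
    """
    df = records.copy()
    raw = df[value_col]

    def _coerce(x):
        if isinstance(x, str):
            s = x.strip()
            if s.startswith("<") or s.upper() in {"LOD", "BLOD", "BELOW LOD"}:
                return 0.0
            return float(s)
        return float(x)

    df[value_col] = raw.map(_coerce)
    if unit_col is not None:
        factors = unit_factors or {}
        unknown = set(df[unit_col]) - set(factors)
        if unknown:
            raise ValueError(f"unconvertible unit(s): {sorted(unknown)}")
        df[value_col] = df[value_col] * df[unit_col].map(factors)
    keys = [k for k in by if k in df.columns]
    return df.groupby(keys, sort=False, as_index=False)[value_col].mean()
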