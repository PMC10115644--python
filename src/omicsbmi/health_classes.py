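"""WHO BMI classes, omics-based misclassification strata and metabolic health.

A participant's measured BMI and each omics-inferred BMI are classified with
the WHO cutoffs (underweight < 18.5, normal [18.5, 25), overweight [25, 30),
obese >= 30 kg/m^2; interior boundaries half-open on the right). A
participant is *mismatched* against an omics category when the two classes
differ. Metabolic health follows the NCEP ATP III operationalization: a
participant with two or more of the four risk components (elevated blood
pressure, triglycerides, low HDL, elevated glucose — each also triggered by
the corresponding medication) is metabolically unhealthy; the label is
undefined unless all four components are assessable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats_core import TestResult

__all__ = [
    "WHO_CUTOFFS",
    "BMI_CLASSES",
    "who_bmi_class",
    "misclassification_strata",
    "misclassification_rate",
    "mets_risk_count",
    "covariate_adjusted_difference",
]

WHO_CUTOFFS = (18.5, 25.0, 30.0)
BMI_CLASSES = ("underweight", "normal", "overweight", "obese")


def who_bmi_class(value):
    """WHO BMI class for a measured or omics-inferred BMI (kg/m^2)."""
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0):
        raise ValueError("BMI must be positive")
    labels = np.select(
        [v < WHO_CUTOFFS[0], v < WHO_CUTOFFS[1], v < WHO_CUTOFFS[2]],
        BMI_CLASSES[:3], default=BMI_CLASSES[3])
    if isinstance(value, pd.Series):
        return pd.Series(labels, index=value.index, name="bmi_class")
    return str(labels) if labels.ndim == 0 else labels


_CLASS_ORDER = {c: i for i, c in enumerate(BMI_CLASSES)}


def misclassification_strata(measured_class, inferred_class) -> pd.DataFrame:
    """Matched/mismatched stratum plus the signed direction.

    ``direction`` is 'above' when the inferred class exceeds the measured
    class in the WHO ordering (metabolically unhealthy direction), 'below'
    for the converse, 'same' when matched.
    """
    m = pd.Series(measured_class)
    o = pd.Series(inferred_class)
    for s in (m, o):
        bad = set(s.dropna().unique()) - set(BMI_CLASSES)
        if bad or s.isna().any():
            raise ValueError(f"undefined BMI class value(s): {sorted(map(str, bad)) or 'NaN'}")
    mi = m.map(_CLASS_ORDER)
    oi = o.map(_CLASS_ORDER)
    stratum = np.where(mi == oi, "matched", "mismatched")
    direction = np.select([oi > mi, oi < mi], ["above", "below"], default="same")
    return pd.DataFrame({"stratum": stratum, "direction": direction},
                        index=m.index)


def misclassification_rate(strata: pd.DataFrame,
                           measured_class=None,
                           scope: str = "overall"):
    """Fraction mismatched, overall or per measured BMI class."""
    s = strata["stratum"] if isinstance(strata, pd.DataFrame) else pd.Series(strata)
    if scope == "overall":
        if len(s) == 0:
            raise ValueError("empty scope")
        return float((s == "mismatched").mean())
    if scope == "per_class":
        if measured_class is None:
            raise ValueError("per-class rate needs the measured classes")
        mc = pd.Series(measured_class).loc[s.index]
        out = (s == "mismatched").groupby(mc).mean()
        return out
    raise ValueError("scope must be 'overall' or 'per_class'")


def mets_risk_count(record, strict_medication: bool = False):
    """NCEP ATP III risk count and metabolic-health label for one record.

    ``record`` is a mapping (or Series) with systolic_bp, diastolic_bp,
    triglycerides, hdl, glucose, sex ('F'/'M'), and optional boolean
    medication flags antihypertensive_med, lipid_med, antidiabetic_med.
    Missing medication flags default to False unless ``strict_medication``,
    in which case the label is undefined. A missing measured component makes
    the label undefined (returned as (None, None)), never zero.
    """
    def get(key):
        v = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    def med(key):
        v = get(key)
        if v is None:
            if strict_medication:
                return None
            return False
        return bool(v)

    needed = ["systolic_bp", "diastolic_bp", "triglycerides", "hdl",
              "glucose", "sex"]
    vals = {k: get(k) for k in needed}
    meds = {k: med(k) for k in ("antihypertensive_med", "lipid_med",
                                "antidiabetic_med")}
    if any(v is None for v in vals.values()) or any(v is None for v in meds.values()):
        return None, None
    hdl_cut = 50.0 if str(vals["sex"]).upper().startswith("F") else 40.0
    risks = [
        vals["systolic_bp"] >= 130.0 or vals["diastolic_bp"] >= 85.0
        or meds["antihypertensive_med"],
        vals["triglycerides"] >= 150.0,
        vals["hdl"] < hdl_cut or meds["lipid_med"],
        vals["glucose"] >= 100.0 or meds["antidiabetic_med"],
    ]
    count = int(sum(risks))
    return count, ("unhealthy" if count >= 2 else "healthy")


def mets_risk_table(metadata: pd.DataFrame,
                    strict_medication: bool = False) -> pd.DataFrame:
    """Vectorized :func:`mets_risk_count` over a metadata table."""
    rows = [mets_risk_count(rec, strict_medication)
            for _, rec in metadata.iterrows()]
    return pd.DataFrame(rows, index=metadata.index,
                        columns=["mets_risk_count", "metabolic_health"])


def covariate_adjusted_difference(outcome: pd.Series, group: pd.Series,
                                  covariates: pd.DataFrame) -> TestResult:
    """OLS coefficient of a binary group indicator, covariate-adjusted.

    ``outcome`` should already be preprocessed (trimmed/transformed/
    standardized); ``covariates`` typically holds BMI, sex, age and ancestry
    PCs. Rows with any missing value are dropped. The caller owns the
    multiple-testing family and applies BH across it.
    """
    from .inferred_bmi import _covariate_design

    df = pd.concat([outcome.rename("_y"), group.rename("_g"), covariates],
                   axis=1).dropna()
    levels = sorted(df["_g"].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"group must be binary, got levels {levels}")
    g = (df["_g"].astype(str) == levels[1]).astype(float)
    C = _covariate_design(df[covariates.columns])
    design = sm.add_constant(np.column_stack([g.to_numpy(), C.to_numpy()]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(df["_y"].to_numpy(dtype=float), design).fit()
    ci = fit.conf_int()[1]
    return TestResult(
        statistic=float(fit.tvalues[1]), p_value=float(fit.pvalues[1]),
        df=float(fit.df_resid), estimate=float(fit.params[1]),
        ci_low=float(ci[0]), ci_high=float(ci[1]))
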