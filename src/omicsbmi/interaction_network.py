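"""Two-stage differential-correlation scan of plasma analyte pairs.

Stage 1 asks, for every unordered analyte pair, whether the cross-sectional
association between the two analytes is modified by the baseline
metabolomics-inferred BMI: a Gaussian identity-link GLM of one analyte on
the other, the (standardized) modifier, their interaction, and sex, baseline
age and ancestry PCs; significance is the two-sided t-test of the
interaction coefficient, BH-adjusted across all scanned pairs. Stage 2
follows the stage-1 survivors longitudinally within the metabolically obese
group (baseline obese inferred-BMI class) with exchangeable-covariance GEEs
per pair, testing the analyte x days-in-program interaction with robust
standard errors, BH-adjusted within the survivor family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .longitudinal import season_of
from .preprocess import select_skew_minimizing_transform, trim_outliers, zscore
from .stats_core import bh_adjust

__all__ = [
    "InteractionEdge",
    "prepare_network_inputs",
    "enumerate_analyte_pairs",
    "stage1_glm_scan",
    "stage2_gee_scan",
    "build_edge_table",
]


@dataclass
class InteractionEdge:
    """One analyte pair with stage-1 (and optionally stage-2) statistics."""

    analyte_i: str
    analyte_j: str
    stage1_beta: float
    stage1_p: float
    stage1_fdr: float
    stage1_n: int
    stage2_beta: float | None = None
    stage2_p: float | None = None
    stage2_fdr: float | None = None
    stage2_n: int | None = None
    stage2_converged: bool | None = None

    @property
    def key(self) -> tuple:
        return tuple(sorted((self.analyte_i, self.analyte_j)))


def prepare_network_inputs(matrices, trim_k: float = 3.0,
                           invariant_tol: float = 0.95):
    """Trim, transform and standardize analyte columns for the scan.

    Per analyte: values beyond +/- trim_k s.d. are blanked, the
    skew-minimizing transform is chosen on the trimmed values, and the
    column is z-scored. Near-invariant columns (a single value occupying
    more than ``invariant_tol`` of non-missing entries, or zero spread) are
    dropped and reported, since they prevent the pair models from
    converging. Returns ``(table, dropped_columns)``.
    """
    if isinstance(matrices, dict):
        frames = [m.values if hasattr(m, "values") and not isinstance(m, pd.DataFrame)
                  else m for m in matrices.values()]
        data = pd.concat(frames, axis=1)
    else:
        data = matrices.copy()
    out = {}
    dropped = []
    for col in data.columns:
        v = data[col].astype(float)
        with warnings.catch_warnings():
            # constant columns warn inside trim_outliers; they are dropped
            # as invariant below anyway
            warnings.simplefilter("ignore", UserWarning)
            try:
                trimmed = trim_outliers(v, k=trim_k)
            except ValueError:
                dropped.append(col)
                continue
        obs = trimmed.dropna()
        top_share = obs.value_counts(normalize=True).iloc[0] if len(obs) else 1.0
        if obs.nunique() < 3 or obs.std(ddof=0) == 0 or top_share > invariant_tol:
            dropped.append(col)
            continue
        _, transformed = select_skew_minimizing_transform(trimmed.to_numpy())
        z, _ = zscore(transformed)
        out[col] = z
    if not out:
        raise ValueError("all analyte columns were dropped as invariant")
    return pd.DataFrame(out, index=data.index), dropped


def enumerate_analyte_pairs(panel) -> list:
    """All unordered analyte pairs; count is n(n-1)/2."""
    ids = list(panel)
    if len(ids) < 2:
        raise ValueError("panel must have at least 2 analytes")
    return list(combinations(ids, 2))


def _scan_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    from .inferred_bmi import _covariate_design
    return _covariate_design(covariates)


def _ols_interaction(y, x, w, C):
    """Interaction coefficient/p from the Gaussian identity-link model
    y ~ x * w + covariates (OLS is the exact ML fit of that GLM)."""
    design = sm.add_constant(np.column_stack([x, w, x * w, C]))
    fit = sm.OLS(y, design).fit()
    return float(fit.params[3]), float(fit.pvalues[3])


def stage1_glm_scan(data: pd.DataFrame, modifier: pd.Series,
                    covariates: pd.DataFrame, pairs=None,
                    orientation: str = "lexicographic",
                    min_n_margin: int = 3) -> list[InteractionEdge]:
    """Cross-sectional interaction scan over analyte pairs.

    For each unordered pair the dependent analyte is the lexicographically
    smaller ID (``orientation='lexicographic'``) or both orientations are
    fit and the larger (conservative) p reported (``orientation='both'``).
    Complete-case per pair; a pair with fewer usable rows than the
    covariate count plus ``min_n_margin`` is skipped. The BH family is the
    set of all fitted pairs.
    """
    if orientation not in ("lexicographic", "both"):
        raise ValueError("orientation must be 'lexicographic' or 'both'")
    pairs = pairs if pairs is not None else enumerate_analyte_pairs(data.columns)
    w_all, _ = zscore(modifier.loc[data.index].to_numpy(dtype=float))
    C_all = _scan_covariates(covariates.loc[data.index]).to_numpy(dtype=float)
    values = data.to_numpy(dtype=float)
    colpos = {c: i for i, c in enumerate(data.columns)}
    min_n = C_all.shape[1] + 3 + min_n_margin
    edges, skipped = [], []
    for a, b in pairs:
        dep, ind = sorted((a, b))
        yi, xi = values[:, colpos[dep]], values[:, colpos[ind]]
        ok = ~(np.isnan(yi) | np.isnan(xi) | np.isnan(w_all)
               | np.isnan(C_all).any(axis=1))
        n = int(ok.sum())
        if n < min_n:
            skipped.append((a, b, f"n={n} below minimum {min_n}"))
            continue
        beta, p = _ols_interaction(yi[ok], xi[ok], w_all[ok], C_all[ok])
        if orientation == "both":
            beta2, p2 = _ols_interaction(xi[ok], yi[ok], w_all[ok], C_all[ok])
            if p2 > p:
                beta, p = beta2, p2
        edges.append(InteractionEdge(dep, ind, beta, p, np.nan, n))
    if edges:
        fdr = bh_adjust([e.stage1_p for e in edges])
        for e, q in zip(edges, fdr):
            e.stage1_fdr = float(q)
    return edges


def stage2_gee_scan(long_data: pd.DataFrame, survivors: list[InteractionEdge],
                    metadata: pd.DataFrame, obese_participants,
                    fdr_threshold: float = 0.05,
                    maxiter: int = 100) -> list[InteractionEdge]:
    """Longitudinal GEE scan of the stage-1 survivors.

    ``long_data`` is long-format with columns participant, day, optionally
    date, and the (baseline-standardized) analyte columns; rows are
    restricted to ``obese_participants`` (the baseline obese inferred-BMI
    class). Each survivor pair gets a GEE of the dependent analyte on the
    other analyte, days, their interaction, and sex/age/PC/season
    covariates with an exchangeable working covariance grouped by
    participant. Non-convergent pairs are flagged and excluded from the BH
    family, which otherwise is exactly the survivor set.
    """
    keep = long_data[long_data["participant"].isin(set(obese_participants))]
    if keep.empty:
        raise ValueError("no longitudinal rows for the metabolically obese group")
    meta = metadata.loc[keep["participant"]]
    cov = pd.DataFrame({
        "sex": (meta["sex"].to_numpy() == "M").astype(float),
        "age": meta["age"].to_numpy(dtype=float),
    }, index=keep.index)
    for pc in ("pc1", "pc2", "pc3", "pc4", "pc5"):
        if pc in metadata.columns:
            cov[pc] = meta[pc].to_numpy(dtype=float)
    if "date" in keep.columns:
        season = season_of(keep["date"]).to_numpy()
        for s in ("MAM", "JJA", "SON"):
            cov[f"season_{s}"] = (season == s).astype(float)
    days = keep["day"].to_numpy(dtype=float) / 365.0
    groups_all = keep["participant"].to_numpy()

    completed = []
    for edge in survivors:
        dep, ind = edge.analyte_i, edge.analyte_j
        y = keep[dep].to_numpy(dtype=float)
        x = keep[ind].to_numpy(dtype=float)
        ok = ~(np.isnan(y) | np.isnan(x) | cov.isna().any(axis=1).to_numpy())
        design = sm.add_constant(np.column_stack(
            [x[ok], days[ok], (x * days)[ok], cov.to_numpy(dtype=float)[ok]]))
        out = InteractionEdge(dep, ind, edge.stage1_beta, edge.stage1_p,
                              edge.stage1_fdr, edge.stage1_n,
                              stage2_n=int(ok.sum()))
        try:
            model = sm.GEE(y[ok], design, groups=groups_all[ok],
                           cov_struct=sm.cov_struct.Exchangeable(),
                           family=sm.families.Gaussian())
            fit = model.fit(maxiter=maxiter)
            out.stage2_beta = float(fit.params[3])
            out.stage2_p = float(fit.pvalues[3])
            out.stage2_converged = True
        except Exception:
            out.stage2_converged = False
        completed.append(out)
    family = [e for e in completed if e.stage2_converged]
    if family:
        fdr = bh_adjust([e.stage2_p for e in family])
        for e, q in zip(family, fdr):
            e.stage2_fdr = float(q)
    return completed


def build_edge_table(edges: list[InteractionEdge]) -> pd.DataFrame:
    """Tabular export with a stable column order and unique unordered keys."""
    rows = []
    seen = set()
    for e in edges:
        if e.key in seen:
            raise ValueError(f"duplicate pair {e.key}")
        seen.add(e.key)
        rows.append({
            "analyte_i": e.analyte_i, "analyte_j": e.analyte_j,
            "stage1_beta": e.stage1_beta, "stage1_p": e.stage1_p,
            "stage1_fdr": e.stage1_fdr, "stage1_n": e.stage1_n,
            "stage2_beta": e.stage2_beta, "stage2_p": e.stage2_p,
            "stage2_fdr": e.stage2_fdr, "stage2_n": e.stage2_n,
            "stage2_tested": e.stage2_converged is not None,
            "stage2_converged": e.stage2_converged,
        })
    return pd.DataFrame(rows, columns=[
        "analyte_i", "analyte_j", "stage1_beta", "stage1_p", "stage1_fdr",
        "stage1_n", "stage2_beta", "stage2_p", "stage2_fdr", "stage2_n",
        "stage2_tested", "stage2_converged"])
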