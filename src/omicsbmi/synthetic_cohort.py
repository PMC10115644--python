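"""Synthetic multiomic cohort generator with known ground truth.

The generator emulates a wellness-cohort design in which metabolomics,
proteomics and clinical-lab panels are measured from the same blood draw,
BMI is roughly evenly split across the WHO normal/overweight/obese classes,
and a latent *metabolic deviation* D drives discordance between measured BMI
and the molecular state. Each signal analyte loads sparsely on centered log
BMI and on D:

    x_j = a_j * y_c + b_j * D + eps_j,    eps_j ~ N(0, noise_sd^2)

where b_j shares a_j's sign with analyte-specific coupling (b_j = a_j *
U(0.7, 1.3)). The shared-sign deviation loadings make every category's BMI
prediction deviate from the measured value in the direction of D — so
Delta-BMI correlates across omics and with metabolic health — while the
coupling spread keeps log BMI identifiable in the noiseless limit. Metabolic-syndrome risk components
(blood pressure, triglycerides, HDL, glucose, medication flags) are monotone
in D; gut-microbiome Dirichlet concentrations shrink with D so alpha
diversity is negatively tied to it; configured analyte pairs have an
association slope that varies linearly with (log BMI + D); and under the
longitudinal intervention the category-specific molecular state decays
toward a healthy reference at per-category response rates.

Everything is a deterministic function of ``GeneratorConfig.seed`` via named
child streams (structure, cohort, visits, microbiome, missingness,
external), so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "OmicsMatrix",
    "TaxonTable",
    "LongitudinalData",
    "generate_baseline_cohort",
    "generate_longitudinal_visits",
    "generate_microbiome_counts",
    "generate_external_cohort",
    "inject_missingness",
    "generative_r2",
    "write_cohort",
]

CATEGORIES = ("metabolomics", "proteomics", "chemistries")
_PREFIX = {"metabolomics": "met", "proteomics": "prot", "chemistries": "chem"}
_STREAMS = {"structure": 0, "cohort": 1, "visits": 2, "microbiome": 3,
            "missing": 4, "external": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the emulated design: 500 participants, panels of
    60/30/10 analytes with 20/8/5 signal analytes, log-normal BMI centered
    so the normal/overweight/obese classes are each roughly a third of the
    cohort, latent deviation s.d. 0.12 on the log-BMI scale, and
    metabolomics the fastest / proteomics the slowest longitudinal
    responder.
    """

    n_participants: int = 500
    panel_sizes: dict = field(default_factory=lambda: {
        "metabolomics": 60, "proteomics": 30, "chemistries": 10})
    n_signal_analytes: dict = field(default_factory=lambda: {
        "metabolomics": 20, "proteomics": 8, "chemistries": 5})
    effect_scale: float = 1.0
    noise_sd: float = 0.35
    latent_deviation_sd: float = 0.12
    discordant_fraction: float = 0.25
    missing_rate: float = 0.0
    visit_schedule: tuple = (0, 183, 365)
    response_rates: dict = field(default_factory=lambda: {
        "metabolomics": 0.30, "chemistries": 0.15, "proteomics": 0.05})
    bmi_response_rate: float = 0.10
    n_taxa: int = 40
    sequencing_depth: int = 10_000
    diversity_effect: float = 1.0
    n_interaction_pairs: int = 5
    interaction_effect: float = 0.3
    bmi_log_mean: float = 3.31   # exp(3.31) ~ 27.4 kg/m^2
    bmi_log_sd: float = 0.21
    healthy_log_bmi: float = 3.114  # exp ~ 22.5 kg/m^2, intervention target
    external_shift: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for cat in CATEGORIES:
            if self.panel_sizes.get(cat, 0) < 1:
                raise ValueError(f"non-positive panel size for {cat}")
            if not 0 <= self.n_signal_analytes.get(cat, 0) <= self.panel_sizes[cat]:
                raise ValueError(f"n_signal_analytes out of range for {cat}")
        for name in ("discordant_fraction",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.latent_deviation_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(d < 0 for d in self.visit_schedule):
            raise ValueError("visits before day 0 are invalid")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")


@dataclass
class GroundTruth:
    """Planted parameters the downstream stages are expected to recover."""

    true_log_bmi: pd.Series
    metabolic_deviation: pd.Series
    signal_support: dict          # category -> {analyte: {"bmi": a, "deviation": b}}
    planted_pairs: list           # [(analyte_i, analyte_j, modifier_effect)]
    mets_component_links: dict    # component -> coefficient on standardized D
    discordant: pd.Series         # |D| above the (1 - discordant_fraction) quantile

    def to_json(self) -> str:
        payload = {
            "true_log_bmi": self.true_log_bmi.round(10).to_dict(),
            "metabolic_deviation": self.metabolic_deviation.round(10).to_dict(),
            "signal_support": self.signal_support,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "mets_component_links": self.mets_component_links,
            "discordant": {k: bool(v) for k, v in self.discordant.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class OmicsMatrix:
    """Participants x analytes numeric table for one omics category."""

    values: pd.DataFrame
    category: str

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.values.mean(),
            "sd": self.values.std(ddof=0),
            "missing_fraction": self.values.isna().mean(),
        })


@dataclass
class TaxonTable:
    """Samples x taxa counts with a taxonomy rank annotation."""

    counts: pd.DataFrame
    rank: str = "ASV"
    sample_to_participant: dict | None = None


@dataclass
class LongitudinalData:
    """Visit-level BMI and analyte tables.

    ``bmi`` has one row per (participant, day); each entry of ``analytes``
    is a category table indexed by the same (participant, day) pairs.
    """

    bmi: pd.DataFrame
    analytes: dict


# ---------------------------------------------------------------------------
# structure: planted coefficients shared by baseline / external generation
# ---------------------------------------------------------------------------

def _draw_structure(config: GeneratorConfig) -> dict:
    rng = _rng(config.seed, "structure")
    panels, support, coef_a, coef_b = {}, {}, {}, {}
    for cat in CATEGORIES:
        p = config.panel_sizes[cat]
        ids = [f"{_PREFIX[cat]}_{i:03d}" for i in range(p)]
        panels[cat] = ids
        n_sig = config.n_signal_analytes[cat]
        sig_idx = rng.choice(p, size=n_sig, replace=False)
        a = np.zeros(p)
        a[sig_idx] = (rng.uniform(0.5, 1.5, size=n_sig)
                      * rng.choice([-1.0, 1.0], size=n_sig)
                      * config.effect_scale)
        # Deviation loadings share the BMI loading's sign but with
        # analyte-specific coupling, so the molecular state leaks into
        # predictions while log BMI stays identifiable in the noiseless
        # limit.
        b = a * 0.0
        b[sig_idx] = a[sig_idx] * rng.uniform(0.7, 1.3, size=n_sig)
        coef_a[cat], coef_b[cat] = a, b
        support[cat] = {
            ids[j]: {"bmi": float(a[j]), "deviation": float(b[j])}
            for j in sorted(sig_idx)
        }
    # Planted modifier pairs live among the null metabolites so they do not
    # interfere with the BMI signal.
    nulls = [panels["metabolomics"][j]
             for j in range(config.panel_sizes["metabolomics"])
             if coef_a["metabolomics"][j] == 0.0]
    n_pairs = config.n_interaction_pairs
    if len(nulls) < 2 * n_pairs:
        raise ValueError("not enough null metabolites for the requested "
                         "number of planted interaction pairs")
    chosen = rng.choice(len(nulls), size=2 * n_pairs, replace=False)
    pairs = [(nulls[chosen[2 * k]], nulls[chosen[2 * k + 1]],
              float(config.interaction_effect)) for k in range(n_pairs)]
    return {"panels": panels, "support": support, "coef_a": coef_a,
            "coef_b": coef_b, "pairs": pairs}


def _apply_planted_pairs(frame: pd.DataFrame, pairs, m_z: np.ndarray,
                         noise_sd: float, rng) -> None:
    """Overwrite pair-target analytes so the slope of x_j on x_i is
    ``effect * m_z`` (linear in the standardized molecular state)."""
    n = len(frame)
    for i_id, j_id, eff in pairs:
        frame[j_id] = (eff * m_z * frame[i_id].to_numpy()
                       + rng.normal(0.0, max(noise_sd, 1e-12), size=n))


def _analyte_tables(config, structure, y_c, deviation, rng) -> dict:
    """Draw one analyte table per category given centered log BMI and D."""
    n = y_c.shape[0]
    m = y_c + deviation
    m_z = (m - m.mean()) / (m.std() or 1.0)
    tables = {}
    for cat in CATEGORIES:
        ids = structure["panels"][cat]
        a = structure["coef_a"][cat]
        b = structure["coef_b"][cat]
        x = (np.outer(y_c, a) + np.outer(deviation, b)
             + rng.normal(0.0, config.noise_sd, size=(n, len(ids))))
        frame = pd.DataFrame(x, columns=ids)
        if cat == "metabolomics":
            _apply_planted_pairs(frame, structure["pairs"], m_z,
                                 config.noise_sd, rng)
        tables[cat] = OmicsMatrix(frame, cat)
    return tables


_METS_LINKS = {  # coefficient on standardized D for each risk component
    "systolic_bp": 8.0, "diastolic_bp": 5.0, "triglycerides_log": 0.35,
    "hdl_log": -0.15, "glucose": 7.0, "antihypertensive_med": 1.2,
    "lipid_med": 1.2, "antidiabetic_med": 1.2,
}


def _metadata_table(config, y_c, deviation, rng) -> pd.DataFrame:
    n = y_c.shape[0]
    d_z = deviation / (config.latent_deviation_sd or 1.0)
    y_z = y_c / (config.bmi_log_sd or 1.0)
    sex = np.where(rng.random(n) < 0.64, "F", "M")
    age = np.clip(rng.normal(47.0, 11.0, n), 21, 80)
    pcs = rng.normal(0.0, 1.0, size=(n, 5))
    draw = pd.to_datetime("2016-01-01") + pd.to_timedelta(
        rng.integers(0, 730, n), unit="D")
    L = _METS_LINKS
    sbp = 118 + L["systolic_bp"] * d_z + 4 * y_z + rng.normal(0, 8, n)
    dbp = 76 + L["diastolic_bp"] * d_z + 2 * y_z + rng.normal(0, 6, n)
    tg = np.exp(np.log(110) + L["triglycerides_log"] * d_z + 0.15 * y_z
                + rng.normal(0, 0.3, n))
    hdl = np.exp(np.log(52) + np.where(sex == "F", 0.09, -0.09)
                 + L["hdl_log"] * d_z - 0.10 * y_z + rng.normal(0, 0.15, n))
    glucose = 92 + L["glucose"] * d_z + 3 * y_z + rng.normal(0, 6, n)
    ldl = np.exp(np.log(115) + 0.10 * y_z + 0.05 * d_z + rng.normal(0, 0.25, n))
    insulin = np.exp(np.log(8) + 0.50 * y_z + 0.40 * d_z + rng.normal(0, 0.4, n))

    def _flag(coef):
        return rng.random(n) < 1.0 / (1.0 + np.exp(-(-2.5 + coef * d_z)))

    meta = pd.DataFrame({
        "sex": sex,
        "age": age,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "pc4": pcs[:, 3], "pc5": pcs[:, 4],
        "draw_date": draw,
        "bmi": np.exp(config.bmi_log_mean + y_c),
        "systolic_bp": sbp,
        "diastolic_bp": dbp,
        "triglycerides": tg,
        "hdl": hdl,
        "ldl": ldl,
        "glucose": glucose,
        "insulin": insulin,
        "antihypertensive_med": _flag(L["antihypertensive_med"]),
        "lipid_med": _flag(L["lipid_med"]),
        "antidiabetic_med": _flag(L["antidiabetic_med"]),
    })
    return meta


def generate_baseline_cohort(config: GeneratorConfig):
    """Generate the baseline cohort.

    Returns ``(omics, metadata, truth)`` where ``omics`` maps category name
    to :class:`OmicsMatrix`, ``metadata`` carries demographics, anthropometry
    and metabolic-syndrome components, and ``truth`` records the planted
    parameters.
    """
    config.validate()
    structure = _draw_structure(config)
    rng = _rng(config.seed, "cohort")
    n = config.n_participants
    idx = pd.Index([f"P{i:04d}" for i in range(n)], name="participant")
    y_c = pd.Series(rng.normal(0.0, config.bmi_log_sd, n), index=idx)
    deviation = pd.Series(rng.normal(0.0, config.latent_deviation_sd, n), index=idx)
    omics = _analyte_tables(config, structure, y_c.to_numpy(), deviation.to_numpy(), rng)
    for cat in CATEGORIES:
        omics[cat].values.index = idx
    meta = _metadata_table(config, y_c.to_numpy(), deviation.to_numpy(), rng)
    meta.index = idx
    if config.discordant_fraction > 0:
        cut = deviation.abs().quantile(1.0 - config.discordant_fraction)
        discordant = deviation.abs() > cut
    else:
        discordant = pd.Series(False, index=idx)
    truth = GroundTruth(
        true_log_bmi=config.bmi_log_mean + y_c,
        metabolic_deviation=deviation,
        signal_support=structure["support"],
        planted_pairs=structure["pairs"],
        mets_component_links=dict(_METS_LINKS),
        discordant=discordant,
    )
    if config.missing_rate > 0:
        for cat in CATEGORIES:
            omics[cat] = inject_missingness(
                omics[cat], config.missing_rate, seed=config.seed)
    return omics, meta, truth


def generate_longitudinal_visits(cohort, config: GeneratorConfig) -> LongitudinalData:
    """Simulate intervention visits for an existing baseline cohort.

    At day t the category-specific molecular state decays toward the healthy
    reference: ``m_c(t) = y_ref + (y0 - y_ref + D) * (1 - r_c * t/365)``
    (floored at 0 elapsed response), and measured BMI decays at
    ``bmi_response_rate``. The day-0 visit reproduces the baseline tables
    exactly.
    """
    omics, meta, truth = cohort
    if len(config.visit_schedule) == 0:
        raise ValueError("visit_schedule is empty")
    if any(d < 0 for d in config.visit_schedule):
        raise ValueError("visits before day 0 are invalid")
    structure = _draw_structure(config)
    rng = _rng(config.seed, "visits")
    idx = meta.index
    y0 = truth.true_log_bmi - config.bmi_log_mean
    dev = truth.metabolic_deviation
    y_ref = config.healthy_log_bmi - config.bmi_log_mean
    elev = (y0 - y_ref).to_numpy()
    m0 = (y0 + dev).to_numpy()
    m0_mean, m0_sd = m0.mean(), m0.std() or 1.0

    bmi_rows = []
    analyte_frames = {cat: [] for cat in CATEGORIES}
    for day in sorted(config.visit_schedule):
        if day == 0:
            bmi_vals = np.exp(truth.true_log_bmi.to_numpy())
            cat_tables = {cat: omics[cat].values.copy() for cat in CATEGORIES}
        else:
            f_bmi = max(0.0, 1.0 - config.bmi_response_rate * day / 365.0)
            y_t = y_ref + elev * f_bmi
            bmi_vals = np.exp(config.bmi_log_mean + y_t
                              + rng.normal(0, 0.01, len(idx)))
            cat_tables = {}
            for cat in CATEGORIES:
                r = config.response_rates.get(cat, 0.0)
                f_c = max(0.0, 1.0 - r * day / 365.0)
                y_t = y_ref + elev * f_c
                d_t = dev.to_numpy() * f_c
                m_t = y_t + d_t
                a = structure["coef_a"][cat]
                b = structure["coef_b"][cat]
                x = (np.outer(y_t, a) + np.outer(d_t, b) + rng.normal(
                    0.0, config.noise_sd, size=(len(idx), len(a))))
                frame = pd.DataFrame(
                    x, index=idx, columns=structure["panels"][cat])
                if cat == "metabolomics":
                    # Pair-modifier structure attenuates as the molecular
                    # state decays (standardized against baseline).
                    m_z_t = (m_t - m0_mean) / m0_sd
                    _apply_planted_pairs(frame, structure["pairs"], m_z_t,
                                         config.noise_sd, rng)
                cat_tables[cat] = frame
        date = meta["draw_date"] + pd.to_timedelta(day, unit="D")
        bmi_rows.append(pd.DataFrame({
            "participant": idx, "day": day, "date": date.to_numpy(),
            "bmi": bmi_vals}))
        for cat in CATEGORIES:
            t = cat_tables[cat].copy()
            t.index = pd.MultiIndex.from_product(
                [[day], idx], names=["day", "participant"]).swaplevel()
            analyte_frames[cat].append(t)
    bmi = pd.concat(bmi_rows, ignore_index=True)
    analytes = {cat: pd.concat(frames).sort_index()
                for cat, frames in analyte_frames.items()}
    return LongitudinalData(bmi=bmi, analytes=analytes)


def generate_microbiome_counts(cohort, config: GeneratorConfig) -> TaxonTable:
    """Dirichlet-multinomial taxon counts whose evenness falls with D.

    All Dirichlet concentrations are scaled by exp(-diversity_effect * D_z),
    so high metabolic deviation yields spikier communities and lower alpha
    diversity.
    """
    _, meta, truth = cohort
    if config.n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if config.sequencing_depth < 1:
        raise ValueError("sequencing depth must be >= 1")
    rng = _rng(config.seed, "microbiome")
    base = np.exp(rng.normal(0.0, 1.2, config.n_taxa))
    base = 50.0 * base / base.sum()
    d_z = (truth.metabolic_deviation
           / (config.latent_deviation_sd or 1.0)).to_numpy()
    counts = np.empty((len(meta), config.n_taxa), dtype=int)
    for i, dz in enumerate(d_z):
        conc = base * float(np.exp(-config.diversity_effect * dz))
        p = rng.dirichlet(np.clip(conc, 1e-6, None))
        counts[i] = rng.multinomial(config.sequencing_depth, p)
    taxa = [f"asv_{i:03d}" for i in range(config.n_taxa)]
    frame = pd.DataFrame(counts, index=meta.index, columns=taxa)
    return TaxonTable(frame, rank="ASV",
                      sample_to_participant={p: p for p in meta.index})


def generate_external_cohort(config: GeneratorConfig, overlap_fraction: float):
    """Generate a second cohort sharing part of the metabolite panel.

    The external cohort keeps the first cohort's planted metabolomics
    coefficients but only exposes ``round(overlap_fraction * panel)`` of its
    metabolite IDs, and draws analytes from per-analyte mean-shifted
    distributions (shift s.d. = ``external_shift``), emulating transfer to a
    cohort measured on a partially overlapping platform.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in (0, 1]")
    structure = _draw_structure(config)
    met_ids = structure["panels"]["metabolomics"]
    n_shared = int(round(overlap_fraction * len(met_ids)))
    if n_shared < 2:
        raise ValueError("overlap yields fewer than 2 shared analytes")
    shared = met_ids[:n_shared]
    rng = _rng(config.seed, "external")
    n = config.n_participants
    idx = pd.Index([f"X{i:04d}" for i in range(n)], name="participant")
    y_c = pd.Series(rng.normal(0.02, config.bmi_log_sd * 1.05, n), index=idx)
    deviation = pd.Series(rng.normal(0.0, config.latent_deviation_sd, n), index=idx)
    omics = _analyte_tables(config, structure, y_c.to_numpy(),
                            deviation.to_numpy(), rng)
    met = omics["metabolomics"].values[shared].copy()
    if config.external_shift > 0:
        shifts = rng.normal(0.0, config.external_shift, len(shared))
        met = met + shifts
    met.index = idx
    meta = _metadata_table(config, y_c.to_numpy(), deviation.to_numpy(), rng)
    meta.index = idx
    truth = GroundTruth(
        true_log_bmi=config.bmi_log_mean + y_c,
        metabolic_deviation=deviation,
        signal_support={"metabolomics": {
            k: v for k, v in structure["support"]["metabolomics"].items()
            if k in set(shared)}},
        planted_pairs=[],
        mets_component_links=dict(_METS_LINKS),
        discordant=pd.Series(False, index=idx),
    )
    return {"metabolomics": OmicsMatrix(met, "metabolomics")}, meta, truth


def inject_missingness(matrix, rate: float, seed: int = 0):
    """Blank entries completely at random at the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    wrapped = isinstance(matrix, OmicsMatrix)
    frame = matrix.values if wrapped else matrix
    if rate == 0.0:
        out = frame.copy()
    else:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 97)))
        mask = rng.random(frame.shape) < rate
        out = frame.mask(pd.DataFrame(mask, index=frame.index,
                                      columns=frame.columns))
    return OmicsMatrix(out, matrix.category) if wrapped else out


def generative_r2(truth: GroundTruth, config: GeneratorConfig,
                  categories=None, analytes=None) -> float:
    """Closed-form R-squared of the best linear predictor of log BMI.

    Computed from the planted joint-Gaussian model, independently of any
    fitted estimator: with X = A*y_c + B*D + eps (plus planted-pair variance
    inflation), R2 = sigma_y^2 * a' Sigma_XX^{-1} a * sigma_y^2 / sigma_y^2.
    """
    cats = list(categories) if categories is not None else list(CATEGORIES)
    ids, a_list, b_list = [], [], []
    for cat in cats:
        for analyte in sorted(truth.signal_support.get(cat, {})):
            if analytes is not None and analyte not in set(analytes):
                continue
            coefs = truth.signal_support[cat][analyte]
            ids.append(analyte)
            a_list.append(coefs["bmi"])
            b_list.append(coefs["deviation"])
    if not ids:
        return 0.0
    a = np.array(a_list)
    b = np.array(b_list)
    s_y2 = config.bmi_log_sd**2
    s_d2 = config.latent_deviation_sd**2
    s_e2 = config.noise_sd**2
    sigma = s_y2 * np.outer(a, a) + s_d2 * np.outer(b, b) + s_e2 * np.eye(len(a))
    cov_xy = a * s_y2
    explained = cov_xy @ np.linalg.pinv(sigma) @ cov_xy
    return float(explained / s_y2)


def write_cohort(cohort, out_dir, taxa: TaxonTable | None = None) -> None:
    """Write analyte tables, metadata, taxon counts and ground truth.

    TSV with participants as rows and a header row of analyte IDs; missing
    values as NA; ground truth as JSON.
    """
    omics, meta, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cat, mat in omics.items():
        mat.values.to_csv(out / f"{cat}.tsv", sep="\t", na_rep="NA")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    if taxa is not None:
        taxa.counts.to_csv(out / "taxa.tsv", sep="\t")
    (out / "ground_truth.json").write_text(truth.to_json())
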