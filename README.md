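# omicsbmi

Toolkit for **omics-inferred BMI** analysis: predicting body-mass index from
blood multiomics (metabolomics, proteomics, clinical laboratory tests) with
cross-validated sparse-regression ensembles, and using the deviation between
the molecular prediction and the measured value to phenotype metabolic
health. It is aimed at computational biologists studying cohorts with
coupled blood-omics panels, anthropometrics and (optionally) gut-microbiome
and longitudinal intervention data.

## The core construct

For each omics category, participants are split once into k = 10 hold-out
sets shared across categories and estimators. For each fold a LASSO model

&nbsp;&nbsp;&nbsp;&nbsp;log<sub>e</sub> BMI ≈ β₀ + Σⱼ βⱼ xⱼ

is trained on the other nine sets (penalty chosen by internal 10-fold CV),
and the held-out participants are scored, so every participant receives
exactly one prediction from a model that never saw them. Predictions are
exponentiated back to kg/m² — MetBMI, ProtBMI, ChemBMI and CombiBMI — and

&nbsp;&nbsp;&nbsp;&nbsp;ΔBMI = (predicted − measured) / measured × 100&nbsp;&nbsp;(% BMI)

quantifies how far a participant's molecular state sits from their
anthropometry. Downstream stages build on this: WHO-class misclassification
strata (matched vs mismatched), NCEP ATP III metabolic-syndrome risk counts
(unhealthy = ≥ 2 of 4 components), gut-microbiome random-forest classifiers
of the measured-BMI vs MetBMI obesity class (compared by unpaired DeLong
test), linear mixed models with truncated-linear time splines (knots at
0/6/12/18 months) for intervention trajectories, and a two-stage
analyte–analyte differential-correlation scan (cross-sectional GLM
interaction with baseline MetBMI; longitudinal GEE interaction with days in
program), both BH-adjusted.

Because cohorts of this kind are access-restricted, the package ships a
first-class synthetic cohort generator with known ground truth: analytes
load sparsely on a molecular state combining log BMI with a latent
metabolic deviation *D*, MetS components are monotone in *D*, microbiome
evenness falls with *D*, planted analyte pairs have association slopes that
vary with metabolic state, and intervention visits decay toward a healthy
reference at omics-specific response rates (metabolomics fastest,
proteomics slowest).

## Worked example

```python
from omicsbmi import synthetic_cohort as sc, inferred_bmi as ib
from omicsbmi.preprocess import zscore

cfg = sc.GeneratorConfig(n_participants=500, seed=1)
omics, meta, truth = sc.generate_baseline_cohort(cfg)

plan = ib.make_split_plan(meta, k=10, seed=1)
Xz, stats = zscore(omics["metabolomics"].values)
ensemble, pred = ib.fit_cv_lasso_ensemble(Xz, meta["bmi"], plan)

print(f"hold-out R^2 = {pred.pooled_r2:.3f}")
print(f"generative oracle R^2 = {sc.generative_r2(truth, cfg, ['metabolomics']):.3f}")
retained, _ = ib.robust_retained_set(ensemble)
print(f"analytes retained in all 10 folds: {len(retained)}")
```

prints

```
hold-out R^2 = 0.672
generative oracle R^2 = 0.697
analytes retained in all 10 folds: 15
```

i.e. the ensemble's hold-out performance (0.67) closely tracks the best
achievable linear R² computed in closed form from the planted generative
model (0.70), and 15 of the 60 metabolites carry nonzero coefficients in
every fold — the robustly retained predictor set.

The same workflow is available from a shell:

```bash
omicsbmi run-all --seed 1 --out my_run     # full pipeline + report.json
omicsbmi simulate --out cohort --n 500     # just the synthetic cohort
omicsbmi fit-measure --cohort-dir cohort --omics metabolomics
```

## Layout

- `src/omicsbmi/synthetic_cohort.py` — cohort generator and ground truth
- `src/omicsbmi/preprocess.py` — missingness filters, forest imputation, skew-minimizing transforms, z-scoring
- `src/omicsbmi/stats_core.py` — BH adjustment, Welch/Pearson tests, out-of-sample R², skewness
- `src/omicsbmi/inferred_bmi.py` — split plans, LASSO/elastic-net/ridge/forest ensembles, model interrogation
- `src/omicsbmi/health_classes.py` — WHO classes, misclassification strata, MetS risk counts
- `src/omicsbmi/microbiome.py` — alpha diversity, PCA features, obesity classifiers, DeLong test
- `src/omicsbmi/longitudinal.py` — spline mixed models and mean trajectories
- `src/omicsbmi/interaction_network.py` — two-stage GLM/GEE differential-correlation scan
- `src/omicsbmi/cli.py` — orchestration and command-line interface

See `docs/methods.md` for the modeling assumptions and design choices.
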