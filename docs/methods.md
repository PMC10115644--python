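# Methods

## The omics-inferred BMI ensemble

Each omics category (metabolomics, proteomics, clinical labs, and their
union) is modeled with a **ten-fold iteration scheme**: one fixed split of
participants into ten near-equal hold-out sets, shared across categories and
estimators so that model performances are comparable fold-by-fold. Per fold,
a LASSO regression of unstandardized log<sub>e</sub>(BMI) (or any positive
measure such as waist-to-height ratio) on the z-scored analytes is fit on
the nine training sets; the penalty is selected by ten-fold internal
cross-validation (mean squared error) over 100 log-spaced candidates
auto-scaled from the training data. The ten hold-out predictions are
assembled into one prediction per participant and exponentiated to measure
units before any classification or ΔMeasure computation. Split balance is
*verified* post hoc (chi-square for categorical covariates, one-way ANOVA
for numeric ones, BH-adjusted) rather than enforced; a stratified
assignment mode exists for callers who want it.

Out-of-sample R² is 1 − SSE/SST with SST about the evaluation set's own
mean, computed on the log scale on which the models are trained (switchable
to a supplied training-mean center). It can legitimately be negative for a
predictor worse than the hold-out mean. Per-fold R² values (n = 10) feed
Welch's t-tests when comparing estimators; the pooled R² over all hold-out
predictions is the secondary summary.

"Retained" means |β| > 1e−12 (absorbing solver noise). The robust retained
set is the intersection of the ten per-fold supports; the union ("retained
in at least one fold") defines the family for the per-analyte explained-
variance scan. The strongest-analyte removal iteration refits the full
ensemble after deleting the robustly retained analyte with the largest
|mean β| (lexicographic ID on exact ties) and stops early with a warning if
the intersection empties. External cohorts are scored with the mean of the
ten fold models on a shared analyte panel standardized with the external
cohort's own statistics; follow-up visits are scored with the one fold
model whose hold-out set contained the participant, on analytes
standardized with baseline statistics — both choices avoid leaking a
participant's own training fold into their score.

Preprocessing follows a two-pass missingness filter (analytes missing in
strictly more than 10% of samples are dropped, then samples missing more
than 10% of surviving analytes), iterative random-forest imputation
(column-wise forests initialized from column means, iterated to a relative-
change tolerance of 1e−4 or 10 rounds; a k-NN mode offers the same contract
at a fraction of the cost), and per-analyte z-scoring. The default mode
imputes and standardizes the whole baseline table before splitting, which
mirrors the classical workflow for this analysis family; the stored-
statistics mechanism supports a leak-free variant that fits statistics
within training folds. Two-step longitudinal imputation imputes baseline
missingness from baseline structure alone, then the remaining visit
missingness from the stacked data, so baseline values never depend on
follow-up.

## Health classification

WHO BMI classes use cutoffs 18.5/25/30 kg/m² with interior intervals
half-open on the right ([18.5, 25), [25, 30), ≥ 30); the boundary
convention is a documented constant because the verbal definitions overlap
at the cutpoints. A participant is *mismatched* against an omics category
when the measured class differs from the inferred class; a signed
direction (inferred above/below measured) is kept as an auxiliary label
because the metabolically unhealthy phenotype corresponds to
inferred-above. Metabolic health uses the NCEP ATP III components —
SBP ≥ 130 or DBP ≥ 85 mmHg or antihypertensive medication;
triglycerides ≥ 150 mg/dl; HDL < 50 (female) / < 40 (male) mg/dl or
lipid-lowering medication; glucose ≥ 100 mg/dl or antidiabetic
medication — with unhealthy = ≥ 2 risks, and the label undefined (never
zero) when any component is missing. Absent medication flags default to
False; a strict mode marks the label undefined instead. Group contrasts
(ΔBMI by health condition, markers by misclassification stratum) are OLS
coefficients of the binary group indicator adjusted for BMI, sex, age and
ancestry PCs; the caller owns the BH family because family bookkeeping
(e.g. 2 classes × 4 categories) is analysis-specific.

## Microbiome classifiers

Alpha diversity is computed at the finest rank: observed richness, Shannon
H = −Σ pᵢ ln pᵢ, and Chao1 = S_obs + n1²/(2 n2). When no doubletons exist
the classical Chao1 is undefined, so the bias-corrected form
S_obs + n1(n1−1)/(2(n2+1)) is used there — a documented deviation from the
printed formula. For group comparisons, richness and Chao1 are square-root
transformed and Shannon squared before z-scoring. Classifier features are
the leading principal components (default 50, clipped to the table's rank)
of per-taxon z-scored log(count+1); the PCA is fit on the full cohort
before splitting, matching the classical (leakage-faithful) workflow, with
per-fold PCA available by fitting on training subsets. The obesity
classifiers are five-fold iteration random forests (stratified folds so
both classes appear in every fold; trees/feature-fraction tuned by internal
CV) emitting a tree-vote binary prediction (ties → normal) and a mean
obese-class probability. The pooled ROC uses all hold-out probabilities;
AUCs of the measured-BMI-class and MetBMI-class classifiers are compared
with the **unpaired** DeLong test (structural-component variances, no
covariance term) because the two classifiers' evaluable participant sets
differ.

## Longitudinal trajectories

Each log-scale measured or inferred BMI series is fit with a linear mixed
model: fixed effects are truncated-linear time splines with knots at 0, 6,
12, 18 months (183/365/548 days at 30.4375 days/month; spline terms with no
variation inside the observed window are dropped to keep the design
nonsingular), sex, baseline age, ancestry PCs 1–5, and Northern-hemisphere
meteorological season of the visit (winter reference); random effects are a
per-participant intercept and slope on days/365 (scaling days stabilizes
the covariance optimization). Estimation is REML with optimizer fallbacks
(lbfgs → cg → powell); persistent non-convergence raises an error naming
the outcome. Misclassification-stratified fits add the binary stratum and
its spline interactions. Mean trajectories hold non-time covariates at
their training means and carry delta-method 95% CIs. Stratified fits are
not produced for the underweight class, whose size does not support
convergence.

## Interaction network

Analytes are prepared by trimming values beyond ±3 s.d. (computed once, no
re-iteration; the boundary is strict, so a value exactly at 3 s.d. is
kept), dropping near-invariant columns (zero spread or one value occupying
> 95% of entries — these prevent the pair models from converging),
selecting per analyte whichever of {identity, log(x − min + 1 when
needed), −√(max + 1 − x)} minimizes |Fisher–Pearson g₁ skewness| (ties
resolve identity > log > mirrored root), and z-scoring. Stage 1 fits, for
every unordered pair, a Gaussian identity-link GLM of the dependent analyte
(lexicographically smaller ID; a conservative both-orientations mode
reports the larger p) on the other analyte, the standardized baseline
MetBMI, their interaction, and sex/age/PC covariates, complete-case per
pair; the interaction coefficient's two-sided t-test is BH-adjusted across
all scanned pairs. The OLS solver is used as the exact maximum-likelihood
fit of that GLM. Stage 2 follows survivors within the baseline obese
MetBMI class using exchangeable-covariance GEEs of analyte on analyte ×
days (days scaled to years) plus covariates and season, robust two-sided p,
BH-adjusted within the survivor family only; non-convergent pairs are
flagged and excluded from the family. Stage-2 visit analytes are
standardized with baseline statistics (without re-selecting the skew
transform), keeping follow-up values on the baseline scale.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised. Defaults: 500 participants; panels of 60 metabolites / 30
proteins / 10 clinical labs with 20/8/5 signal analytes; BMI log-normal
with meanlog 3.31 and sdlog 0.21, which puts roughly a third of the cohort
in each of the normal/overweight/obese classes with ~2% underweight; a
latent metabolic deviation D ~ N(0, 0.12²) on the log-BMI scale; analyte
noise s.d. 0.35. Signal analytes load as xⱼ = aⱼ·y + bⱼ·D + ε with
aⱼ = ±U(0.5, 1.5) and bⱼ = aⱼ·U(0.7, 1.3): the sign-shared deviation
loadings make every omics category's prediction deviate from measured BMI
in the direction of D (so ΔBMI deviations correlate across categories and
with metabolic health), while the analyte-specific coupling keeps log BMI
identifiable — in the noiseless limit the generative system is rank-2 and
the best linear predictor attains R² = 1. Under the defaults the
closed-form generative R² for metabolomics is ≈ 0.70, computed from the
joint-Gaussian conditional variance (Σ_yX Σ_XX⁻¹ Σ_Xy / σ_y², with the
planted-pair variance inflation on the affected columns) — this closed form
is the oracle every recovery test compares against, independent of any
fitted estimator.

MetS components are linear (continuous markers) or logistic (medication
flags) in standardized D with physiologic intercepts chosen so that ~30–35%
of the cohort carries ≥ 2 risks, keeping both health classes populated.
Planted interaction pairs live among null metabolites: the target analyte
equals effect × (standardized molecular state) × source analyte + noise, so
the pair's association slope is linear in log BMI + D (default effect 0.3).
Microbiome counts are Dirichlet-multinomial (40 taxa, depth 10,000) with
all concentrations scaled by exp(−D_z), tying evenness negatively to D.
Intervention visits (days 0/183/365) decay the participant's elevation
above a healthy reference (log 22.5 kg/m²) and their deviation at
per-category rates — metabolomics 0.30/yr, clinical labs 0.15/yr,
proteomics 0.05/yr, measured BMI 0.10/yr — reproducing the
fast-metabolome / slow-proteome response ordering; the day-0 visit
reproduces the baseline tables exactly. Planted-pair structure persists at
visits with the modifier standardized against baseline, so pair
associations attenuate as the molecular state improves. One global seed
expands into named child streams (structure, cohort, visits, microbiome,
missingness, external), so any stage can be regenerated independently and
identical configurations are byte-identical.

What the generator does **not** emulate: batch effects and
limit-of-detection censoring, analyte–analyte residual correlation beyond
the planted pairs, compositional constraints, twin/family structure, and
non-linear analyte–BMI relationships. Tests passing on this cohort
therefore demonstrate correctness of the estimation machinery and sign-level
reproduction of the qualitative phenomena, not performance figures
transferable to real cohorts.

## Numerical choices and problem sizes

- BH adjustment is the exact step-up (cumulative minimum of p·m/rank),
  cross-checked against an independent implementation in tests.
- Welch's t uses Satterthwaite df; identical constant samples return
  t = 0, p = 1 rather than 0/0.
- Random-forest grids default to trees ∈ {100, 300} × features ∈ {√p, 0.3};
  tests and the pipeline use reduced grids, which changes runtime, not
  contracts.
- The suite and the acceptance script run the full design at n = 300–500
  participants, 100-analyte combined panels, 40 taxa, three visits and a
  1,770-pair metabolomics scan — sizes chosen so the whole study remains a
  desk-scale, single-CPU computation while keeping every recovery test
  well-powered.
- Parameter-recovery tolerances follow the planted effects: hold-out R²
  within ±0.1 of the closed-form oracle; sign-level reproductions required
  in ≥ 8 of 10 seeds; FDR calibration bounded by the binomial tolerance of
  the number of null scans.

## Known limitations

- The iterative forest imputer is quadratic-ish in panel width; for wide
  panels the k-NN mode or fewer trees are the practical choices.
- GEE standard errors assume enough clusters (participants) per scan;
  stage 2 on very small obese subgroups can be anti-conservative.
- The misclassification rate on synthetic data (~35%) depends directly on
  the configured deviation scale; it is a property of the simulation
  conditions, not an estimate of any real cohort's rate.
- `mean_trajectory` extrapolates linearly beyond the last knot with
  variation; callers should keep day grids inside the observed window.
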