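# Methods

## Scope and data model

`riskstrat` implements three rule-based risk classifiers (CAD, T2D,
hypertension) with their full evaluation layer, on a fixed-unit cohort
table: concentrations in mmol/L (hs-CRP mg/L), blood pressure in mmHg,
HbA1c in NGSP percent (IFCC mmol/mol accepted on input and converted via
NGSP% = 0.09148·IFCC + 2.152). Units are never auto-detected — silent
unit errors dominate risk-score bugs, so a file in the wrong units fails
validation rather than producing plausible nonsense. Row validation is
total: every ingested row lands either in the cohort or in the rejection
log with a reason.

## Baseline eligibility

Per-condition analysis cohorts exclude, at baseline: a physician
diagnosis of the condition; at least grade-1 hypertension (SBP ≥ 140
and/or DBP ≥ 90 mmHg); fasting glucose above 7.0 mmol/L; impaired kidney
function; and any missing mandatory variable. The kidney criterion is
implemented as eGFR < 60 mL/min/1.73 m² or ACR > 3 mg/mmol. These are
conventional KDIGO-style cutoffs standing in for guideline-based
age-dependent functions that are not numerically specified; both are
configurable and the default is explicitly a substitute, not a citation.
Whether the blood-pressure/glucose exclusions apply to all three cohorts
or only the matching one is configurable; the default applies them
globally, consistent with excluding anyone who crossed *any* clinical
threshold.

## Clinical risk equations

Coefficients live in swappable delimited-text data files, so a score can
be audited or replaced without code changes.

* **CAD**: the sex-specific continuous Framingham general cardiovascular
  function (D'Agostino et al. 2008), `risk = 1 − S₀^exp(lp − mean_lp)`
  with log-transformed age, total and HDL cholesterol (converted to
  mg/dL), treated/untreated SBP, smoking and diabetes terms.
* **T2D and HTN**: logistic equations with the predictor sets of the
  Framingham Offspring 8-year diabetes "simple clinical model" and the
  Framingham hypertension score respectively. Their coefficient files
  are **synthetic stand-ins** (labelled as such in the filename and file
  header): the functional form and predictors match the published
  scores, but the coefficients were calibrated once to give plausible
  absolute-risk distributions in a population with the default
  biomarker marginals — the T2D median 8-year risk near 2.5 % with mass
  on both sides of the 3 %/8 % cutpoints, and roughly 80 % of a
  prehypertensive cohort above the 10 % hypertension cutpoint (matching
  the reported behaviour of the published score in comparable cohorts).
  For real use, transcribe the published coefficients into the same file
  format.

Categories: T2D < 3 % / 3–8 % / > 8 %, HTN < 5 % / 5–10 % / > 10 %, with
boundaries belonging to the intermediate category (the verbal definitions
"<3 %, 3 % to 8 %, and >8 %" imply closed intermediate intervals). CAD
uses tertiles of the analysis-cohort distribution, computed within sex
(the CAD score is reported sex-specifically); ties get average ranks and
resolve toward the lower tertile. Ages outside the CAD score's published
30–74 validity range are clamped with a warning (configurable to error).

## Polygenic scores

Scoring is the plain additive model over a pre-computed weight table;
LD correction is assumed done upstream (the package consumes LDpred-style
output, it does not re-estimate weights). Variant QC keeps
`info ≥ min_info` (default 0.4 — "below 0.4" is an exclusive removal).
Missing dosages are imputed as 2 × effect-allele frequency; a variant
with neither dosages nor a frequency is an error, never silently dropped.
No allele flipping is attempted: dosage columns must be keyed by variant
id with the stated effect allele, and mismatches are errors.

Deciles (10 = highest score) use average ranks; a tied block is assigned
the decile of its average rank, and the degenerate all-tied input
collapses to decile 1 with a warning — determinism was prioritised over
any particular tie aesthetics. Genetic risk groups: decile 10 "high",
8–9 "elevated", 1–7 reference. Deciles are computed per analysis cohort,
after exclusions. The rule engines consume raw-score deciles by default;
covariate-adjusted scores — the linear predictor of a logistic model of
the outcome on PRS, genotyping array, four principal components, age and
sex (a residual-on-covariates mode is available behind a flag) — are used
for the decile hazard-ratio table, and the covariates-only (age and sex)
model is available as a comparison predictor. Zero-variance covariate
columns are dropped before fitting; separation or non-convergence raises
with diagnostics.

## Rule engines

Threshold semantics follow the verbal definitions: "above x"/"below x"
strict, "130 to 139"-style ranges closed. Where the verbal rules leave a
range unspecified, conventional guideline cutpoints are the defaults and
everything sits in `RuleConfig`: triglycerides out of range > 1.7 mmol/L,
hs-CRP > 3 mg/L, overweight/obese BMI ≥ 25 kg/m². "Glucose unregulated"
in the T2D conjunctive rule is read as the elevated glycaemic state
defined in the same sentence (HbA1c 5.5–6.4 % or glucose
5.6–6.1 mmol/L); the alternative reading of that comma list as three
separate decisive rules is exposed as a config switch
(`conjunctive_high_rule=False`) since it would classify every
clinical-high participant HIGH. "Clinical risk elevated" maps to the
intermediate Framingham category. The low-risk arms use per-condition
reference-range sets (CAD: TC ≤ 5.0, LDL ≤ 3.0, HDL ≥ 1.0, TG ≤ 1.7,
hs-CRP ≤ 3, SBP < 130; T2D: glucose < 5.6, HbA1c < 5.5, BMI < 25,
HDL ≥ 1.0, TG ≤ 1.7; HTN: SBP < 130, DBP < 80, BMI < 25), all
configurable because no complete normal-range enumeration accompanies the
verbal rules. Every satisfied clause is recorded in `fired_rules`, so any
classification can be replayed. Only HIGH maps to "advised lifestyle
intervention"; CLINICAL participants are referred to care instead.

## Evaluation layer

AUROC uses the midrank Mann–Whitney statistic — the only construction
that is well defined for a three-level ordinal classifier — with a
percentile bootstrap CI (default B = 2000) stratified by event status so
no resample is single-class; the seed is mandatory wherever resampling
happens. AUROC differences use DeLong's paired variance estimate
(significance convention p < 0.01; stratum contrasts p < 0.05). The NRI
is the two-category form at the advised dichotomy, with the standard
asymptotic variance; this choice is validated by the acceptance suite,
where the asymptotic Wald intervals reproduce the published confidence
intervals of the worked examples to the printed precision (a bootstrap
CI is available for cross-checking). Zero-denominator metrics are
flagged undefined rather than silently NaN. A config flag can floor
zero-event cells at 1 for ratio statistics, replicating the published
tables' footnote convention.

Stratum hazard ratios come from Cox partial likelihood with Efron tie
handling (appropriate for the heavy ties that coarse-resolution event
times produce) delegated to lifelines, with an independent grid-search
partial-likelihood oracle guarding the delegation in the tests. Stratum
HRs are unadjusted (stratum only) by default, with an optional covariate
list; the decile contrasts default to proportional hazards, with a
logistic odds-ratio mode for parity with analyses that report decile
effects from logistic models. A stratum with zero events (or a penalised
rescue fit) is flagged `degenerate` rather than silently exploding.
Absolute risks are Kaplan–Meier 1 − S(horizon) per stratum.

## Synthetic cohort

The generator emulates what the analysis *assumes*, at desk scale:

* biomarker marginals of a middle-aged population cohort (age 56.3 ± 7.6,
  SBP 138 ± 19, DBP 82 ± 10, total cholesterol 5.71 ± 1.1, HDL
  1.47 ± 0.38, glucose 5.0 ± 1.0, HbA1c 35.2 ± 5.3 mmol/mol, BMI
  26.8 ± 4.35, 51.2 % female; triglycerides, hs-CRP and ACR lognormal to
  respect skew and positivity);
* a latent "metabolic" factor loading on BMI, triglycerides, glucose,
  HbA1c and SBP (loadings 0.55/0.40/0.45/0.40/0.30), so compound rules
  see realistically co-elevated markers;
* per-parent Bernoulli family history (one-parent prevalences 41.8 %
  CAD, 16.8 % T2D, 42.7 % HTN) and categorical smoking (5.6 % current,
  0.3 % recently quit);
* genetics: 1,000 variants by default (scoring is linear, so variant
  count adds nothing to correctness beyond scale), allele frequencies
  uniform on (0.05, 0.95), dosages binomial(2, f), mean-zero normal
  weights, imputation-quality scores uniform on (0.3, 1) so the default
  QC filter has work to do. No LD structure and no population
  stratification are simulated; principal components are independent
  standard normals provided for the adjustment API.
* events: exponential (constant-baseline-hazard) proportional hazards
  with linear predictors over centred risk factors plus the standardised
  PRS, administratively censored at 8.8 years. A constant hazard is the
  simplest model consistent with a single reported cumulative-incidence
  horizon; nothing downstream assumes more. Default baseline hazards
  (CAD 0.0010, T2D 0.0015, HTN 0.0060 events/person-year) and per-SD PRS
  hazard ratios (1.8, 1.6, 1.35) were chosen once to give
  order-of-magnitude cumulative incidences of roughly 1.4 %, 2.3 % and
  7 % in the respective analysis cohorts — order of magnitude, not exact
  counts, is the stated goal.

Everything is deterministic given the config seed (independent child
streams per stage, so adding a stage never reshuffles another), and a
truth record keeps each participant's true PRS and linear predictors for
recovery tests. What passing tests on this generator show is that the
*pipeline machinery* is correct — scoring, binning, rule logic, metrics
and survival fits recover known inputs. They do not show that the rule
models discriminate well in real data: the generator has no LD, no
ancestry structure, no measurement error, no informative censoring, and
its clinical-score stand-ins are not the published calibrations.

## Problem sizes and numerical choices

The default desk-scale run is 40,000 participants × 1,000 variants with
B = 200 bootstrap resamples (≈ 15 s on one CPU; B = 2000 is the
configured default for standalone metric calls). The test suite uses
2,000–20,000-participant cohorts, and the stochastic recovery checks use
50 seeded replicates of 4,000 participants: a two-level stratum effect of
HR 4 and the top-decile-vs-rest contrast implied by a per-SD effect of
ln 2 (closed form E[e^{βZ}|top]/E[e^{βZ}|rest] for standard-normal Z,
valid in the rare-event regime the simulation stays in) must each be
covered by the fit's own 95 % CI in ≥ 90 % of replicates. Reported
floats are serialised at 10 significant digits, which makes
write→read→write a byte-identical fixed point; report JSON is
key-sorted, so identical config + seed reproduces runs bit-for-bit.

## Known limitations

* The T2D and HTN clinical-score coefficient files are synthetic
  stand-ins (see above); absolute clinical risks for those two
  conditions are only structurally, not numerically, meaningful until
  the published coefficients are transcribed.
* No competing risks, time-varying covariates or frailty; no 3×3
  category NRI, IDI or calibration statistics; no LD-aware weight
  re-estimation, allele flipping or GWAS harmonisation.
* The adjusted-PRS definition (outcome-model linear predictor) reuses
  the outcome; it mirrors the analysis it reimplements and is kept out
  of the default rule-engine path, which uses raw-score deciles.
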