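# Methods

## The question and the design

Patients with low LDL cholesterol (LDL-C) who are admitted to hospital with
infection have, crudely, a higher risk of sepsis. The epidemiological
question is whether LDL-C lowers sepsis risk *directly* or whether the
association is confounding by comorbid illness — sicker patients have both
lower LDL-C and worse infection outcomes. The package implements the full
observational design that separates the two explanations:

1. an **infection cohort**: adult admissions carrying an infection billing
   code plus an antibiotic within one day of admission (days −1, 0, +1),
   reduced to one index episode per patient;
2. a **qualifying baseline LDL-C** per patient, deliberately anchored more
   than one year before the index admission and scrubbed of values taken
   while ill (inpatient values, values near hypoalbuminaemia, values after
   statin initiation, values under age 18), summarised as the median;
3. a rule-based **sepsis phenotype** within days −1..+1 of admission:
   explicit severe-sepsis/septic-shock codes, or any of five
   organ-dysfunction criteria (cardiovascular, respiratory, renal, hepatic,
   hematologic) judged against per-patient baseline organ function;
4. **comorbidity covariates**: binary modified Charlson/Deyo category
   indicators built from diagnosis codes in the year before admission via a
   phecode grouping, diabetes categories merged, used as independent
   covariates (never as a summed score);
5. an **LDL-C genetic risk score** (GRS), the weighted sum of effect-allele
   dosages over 81 independent LDL-associated SNPs — an instrument for
   lifelong LDL-C that illness cannot confound;
6. **logistic models** of sepsis, ICU admission and in-hospital death on the
   standardised predictor (OR per 1-SD; quartiles against the highest
   quartile), unadjusted and adjusted.

The expected signature of pure confounding is a crude OR per SD below 1
that attenuates to the null once comorbidity indicators enter the model,
together with a null GRS association throughout.

## Synthetic cohorts

Real EHR data of this kind are not publicly deposited, so the package ships
a first-class generator (`ldlsepsis.simulate`) that emits the five linked
tables plus genotypes with the confounding structure the analysis assumes.
Per patient:

* **Comorbidity burden** B: independent Bernoulli draws over the Charlson
  categories (defaults near the prevalences seen in infection cohorts, e.g.
  COPD 0.27, diabetes 0.25+0.08, CHF 0.22), counted over *merged*
  categories so the confounder and the covariate model coincide.
* **LDL-C**: `ldl = μ + g + shift·(B − E[B]) + ε`, with μ = 103.4 mg/dL and
  total SD fixed at 32.6 mg/dL. The genetic part g is the raw weighted
  allele score rescaled so its variance is exactly `grs_target_r2` (default
  0.058) of the total; the residual ε absorbs what the genetic and burden
  parts do not. `shift` defaults to −5.5 mg/dL per active category, chosen
  by the omitted-variable closed form (crude log-OR ≈ β_C·shift·Var(B)/σ_L)
  so the crude association lands at OR ≈ 0.86 per SD, the regime this
  design is meant to interrogate.
* **Outcomes**: `logit P(outcome) = logit(base) + β_C·B + β_L·z(ldl)` with
  β_C = 0.65 per category and β_L (`direct_ldl_logor_per_sd`) defaulting to
  0 — the no-direct-effect world. Base rates (0.05 / 0.025 / 0.006) put the
  marginal rates near 15% sepsis, 10% ICU, 2% death in the measured cohort.
* **Events**: every patient receives an index admission with an infection
  code and an antibiotic on a day in {−1, 0, +1}; comorbidity diagnosis
  codes in the lookback year; outpatient LDL draws (measurement SD
  5 mg/dL) strictly more than a year pre-index; HDL/triglyceride/BMI
  values; statin starts (25% of patients, always after their first LDL);
  occasional low-albumin episodes adjacent to an LDL; and a pre-admission
  creatinine/bilirubin/platelet panel. Sepsis cases get the minimal event
  evidence for exactly one detection pathway, chosen uniformly among the
  six; background noise events are drawn from ranges that can never trip a
  criterion, so detection is exact by construction.
* **Genotypes**: Hardy–Weinberg binomial dosages over the shipped synthetic
  81-SNP weight table (no linkage disequilibrium).

What the generator does *not* emulate — code co-occurrence structure,
billing realism, LD between SNPs, drifting lab assays, informative missing
data — bounds what green tests mean: they demonstrate that the pipeline
recovers the truth of a world with exactly the modelled confounding
structure, not that it would be unbiased on any real EHR.

## Numerical and convention choices

* Dates at day resolution; relative day = event date − admission date.
* "More than 1 year before" is strictly > 365 days; the albumin window is
  ±30 days inclusive in both directions; a same-day LDL and first statin
  counts as statin-exposed.
* Organ-dysfunction baselines are extrema over [admission − 365 d,
  discharge] *including* the event window, so a single in-window lab can
  never satisfy a doubling criterion by itself.
* Doubling and 50%-decline thresholds are inclusive (≥ 2×, ≤ 0.5×); the
  platelet low cut (< 100) and its baseline floor (≥ 100) follow the
  surveillance wording exactly; hepatic requires the absolute 2.0 mg/dL cut
  *and* doubling.
* Index-episode ties break by admit date then lexicographic infection code;
  closest-to-admission ties go to the earlier measurement.
* Predictors are standardised by the analysis cohort's SD (ddof = 1) after
  listwise deletion, so "per 1-SD" is cohort-relative; the identity
  exp(β_raw·SD) = OR_per-SD holds to 1e-8 and is tested.
* Quartile cuts are linear-interpolation 25/50/75 percentiles, ties to the
  lower quartile, highest quartile as reference.
* Logistic fits use Newton MLE with an L-BFGS fallback for sparse-event
  quasi-separation; Wald 95% CIs and two-sided Wald p-values (the CI method
  is a package choice; profile likelihood was considered and not needed at
  these event counts). Constant design columns (e.g. the four structurally
  absent comorbidity categories in the measured cohort) are dropped with a
  log notice.
* Significance uses α = 0.0167 (three outcomes), stored in config.
* Missing genotype dosages are mean-imputed as 2·maf; SNPs absent from the
  genotype matrix are skipped with a warning.
* Index selection for the measured cohort uses the latest LDL passing the
  index-independent rules as the episode cutoff, then applies the full
  (index-dependent) one-year rule to the chosen episode — "first episode
  after a qualifying measurement" without the circularity of a rule that
  references the index it is selecting.

## Replicate-based verification

Because the real cohort cannot be re-analysed, correctness is demonstrated
as recoverable properties, at the problem sizes the package adopts as its
simulation conditions (200 replicates; n = 4000 for the attenuation
property, n = 8000 for effect recovery and GRS calibration):

* the vectorised phenotyper agrees 100% with an independent loop-based
  transcription of the rules on 10,000 randomized boundary-stressing
  episodes;
* each of the six planted evidence pathways is detected as exactly that
  pathway;
* with no direct effect, the crude OR is significantly protective in ≥80%
  of replicates while the adjusted CI covers the null in ≥90% (measured:
  ~85% and ~94%);
* an injected direct log-OR of −0.15 per SD is recovered by the adjusted
  model to within ±0.05 on average;
* the GRS explains 5.8% ± 1.0 of LDL variance (r ≈ 0.24) against measured
  baselines, averaged over five replicate cohorts.

## Known limitations

Exact ICD/phecode content is illustrative (the real supplementary lists are
not published); the generator's single-admission default makes the
no-prior-infection sensitivity cohort coincide with the primary cohort
unless multi-episode generation is enabled; no survival or competing-risk
modelling; no formal instrumental-variable (mendelian-randomisation)
estimation beyond the GRS association itself.
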