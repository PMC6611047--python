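# Methods

## The development pipeline

The package reconstructs, on synthetic data, the development of a
rule-based triage algorithm for primary-care sciatica.  The outcome
throughout is *referral to spinal specialist services within 12 months*
(binary).  Development proceeds in the published order:

1. **Eligibility** — patients diagnosed with sciatica at diagnostic
   confidence ≥ 70% (inclusive) form the analysis sample; records with
   missing confidence are excluded and counted separately.
2. **Descriptives** — means/SDs and counts/percentages by referral
   status, complete-case per variable.
3. **Factor selection** — candidate factors grouped into five domains
   (impact of condition; pain levels/symptoms; psychological
   perceptions; symptom behaviour and presentation; clinical
   examination findings).  Per domain: univariable logistic fits; a
   collinearity screen; a within-block multivariable model whose
   significant factors progress; finally an overall model with backward
   elimination (drop the least significant, refit, stop when all
   p < 0.05).  p = 0.05 exactly counts as not significant.
4. **Internal validation** — apparent AUC (DeLong CI), 500-replicate
   enhanced-bootstrap optimism correction, calibration slope.
5. **Algorithm** — three fast-track scenarios evaluated against observed
   referral; the adopted rule combines prognostic risk (STarT Back) with
   the count of four clinical characteristics and is identical to the
   group-3 arm of the allocation algorithm.

## Statistical choices

* **2×2 odds ratios.** OR = ad/bc with Wald CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  A zero cell (with positive
  margins) triggers the Haldane–Anscombe +0.5 correction, flagged in the
  result; a zero margin is an error.  The closed form agrees with a
  univariable logistic fit to ≤ 1e−6 relative error (tested).
* **Collinearity screen.** Pairwise correlations are type-appropriate:
  Spearman when either variable is ordinal, otherwise Pearson (the
  point-biserial coefficient for binary variables).  For each pair with
  |r| > 0.7 one variable is dropped — never a *forced survivor*, the
  mechanism by which one representative of a correlated block is chosen
  on clinical grounds (default: current leg pain for the pain/symptom
  block).  Survivors with VIF > 5 are then dropped.  Constant variables
  are dropped with reason "zero variance".
* **Categorical factors.** Pin-prick sensation enters models as a
  3-level factor (normal reference), reflexes as 4-level, duration as
  3-level.  A factor's significance is judged by the *minimum Wald p
  across its levels*: the factor is retained whenever any level shows an
  effect.  This matches how the development analysis evidently read its
  output — its final model keeps sensation with one significant level
  (loss) and one non-significant sibling (reduced); a joint 2-df test of
  those printed coefficients would not have reached p < 0.05.  The cost
  is a mildly anticonservative factor-level type-I rate (~10% for a
  2-df factor), which the simulation tests account for.
* **Separation.** Logistic fits are maximum likelihood (statsmodels);
  non-convergence, non-finite estimates or |coefficient| > 50 raise a
  separation error.  Selection flags such variables and continues;
  bootstrap replicates that separate are discarded and counted, with a
  warning above 10%.
* **AUC and optimism.** AUC is the pairwise concordance probability
  (ties 0.5), with a DeLong 95% CI (verified against an independent
  reference implementation to 1e−10).  The enhanced bootstrap resamples
  patients (rows), refits the full model each replicate, and estimates
  optimism as mean(train AUC − test-on-original AUC); corrected AUC =
  apparent − optimism at full precision (rounding only at display).
  The CI for the bootstrap mean is a normal approximation over replicate
  values.
* **Calibration slope.** Coefficient from a logistic refit of the
  outcome on the linear predictor (log-odds scale).  On the development
  data of a maximum-likelihood fit the slope is exactly 1 (score
  equations), which the tests assert to 1e−6; on fresh data an overfit
  model shrinks below 1 (tested by simulation).
* **Proportion CIs.** Sensitivity/specificity/PPV/NPV use Clopper–
  Pearson exact intervals.  The reference tables' printed intervals are
  reproduced by the exact method in 9 of 10 cells (e.g. sensitivity
  39/57 → (55–80)), while Wilson matches only 4, so exact was adopted.
  Metrics with a zero denominator are reported as undefined rather than
  0/0.
* **Allocation with partial information.** A patient with indeterminate
  characteristic flags is still allocated when every possible
  characteristic count yields the same group (low risk ⇒ group 1; three
  definite positives at high risk ⇒ group 3); otherwise allocation is
  refused and the patient is excluded (complete-case) from rule
  evaluation.

## The synthetic cohort generator

The generator emulates the development study's conditions; its defaults
are the study's published figures and are not tuned per experiment.

**Structure.** One latent severity factor z ~ N(0,1) per patient drives
all severity-related fields:

* Integer rating scales are discretised clipped normals
  round(μ + a·z + ε).  The nine pain/bothersomeness items (the
  "pain levels/symptoms" domain) share 90% of their SD with z, giving
  pairwise |r| ≈ 0.75 after discretisation — the screen's > 0.7
  threshold fires for every pair, as described for the source data.
* Binary and ordinal fields follow logistic / cumulative-logistic
  models in z whose intercepts are solved by 80-node Gauss–Hermite
  quadrature so each marginal matches its target exactly in
  expectation.  Latent loadings are structural constants chosen so the
  *unadjusted* exposure–referral odds ratios land near the published
  ones (see below).
* STarT Back item prevalences were solved (quadrature plus a
  Bernoulli-sum convolution) so the low/medium/high mix is
  0.116/0.484/0.400 — the published distribution normalised over
  complete screening tools.  Because the psychological subscale is a
  subset of the total, high risk ⇔ psychological score ≥ 4, which makes
  this calibration exact.
* Diagnostic confidence is normal with mean set so
  P(confidence ≥ 70) equals the eligible fraction (429/609 by default).
* Referral is drawn from a logistic model in the four characteristics
  plus medium/high risk indicators (conditional ORs 2.08, 1.75, 1.85,
  1.45, 3.5, 4.1; intercept −4.49).  These conditional defaults were
  calibrated once, at n = 300k, so that the implied *marginal* 2×2 odds
  ratios approximate the published unadjusted ones (impact 2.6 vs 2.64;
  binary sensory 2.0 vs the 1.9 implied by the baseline table) and the
  referral prevalence is 13.3%.  A single binary sensory coefficient
  cannot reproduce both level-specific rows (reduced 1.74, loss 2.61);
  the aggregate was prioritised.
* Missingness is MCAR, by default 2% on each neurological-examination
  field, matching the "small proportion of missing data" in the source
  tables; rates are configurable per column.

**What it does not emulate.** Real cohorts have structured (non-MCAR)
missingness, multi-factor dependence beyond a single severity axis,
item-level response styles, and referral decisions influenced by
unmeasured clinical context.  Passing tests therefore demonstrate that
the *pipeline* behaves correctly under known generating conditions —
recovery of generating coefficients, correct screen behaviour, correct
metric arithmetic — not that the algorithm would perform identically on
new clinical data.

**Determinism.** All randomness flows through one
`numpy.random.default_rng(seed)`; identical (config, seed) yields a
byte-identical cohort.

## Simulation findings the tests encode

* Refitting the generating model on large cohorts (n = 4000) covers each
  generating log-odds coefficient with its 95% CI at ≥ 90% across
  replicates.  At the study's own size (n = 429, ~57 events) the model
  quasi-separates in roughly a third of replicates (zero referred
  low-risk patients) — a realistic sparse-event phenomenon; such fits
  are flagged and excluded.
* Backward elimination at n = 429 retains the three generating
  characteristics in a majority of replicates and drops pain
  self-efficacy (which carries no conditional effect in the generator)
  in the large majority — but retention of the weakest factor
  (sensation) is near 60%, i.e. the published single-cohort selection
  would not replicate reliably at this sample size.
* Bootstrap optimism on n = 429 cohorts is positive and of order
  0.01–0.05, placing the corrected AUC below the apparent AUC, the
  direction and magnitude expected at this events-per-variable ratio.

## Problem sizes

Defaults used by the tests and drivers: screened cohorts of 609;
analysis cohorts of 429 eligible; 500 bootstrap replicates; 200
selection replicates; 120 recovery replicates at n = 4000; marginal
convergence checked on one cohort of 120k screened.  These sizes give
Monte-Carlo error comfortably below every asserted tolerance.

## Known limitations

* The generator's between-domain dependence is a single factor; real
  correlation structure is richer.
* Backward elimination and min-Wald factor tests are reconstructions of
  the development analysis (which did not specify its elimination order
  or factor-level test); both choices are recorded here and in the
  selection trace rather than hidden.
* No external validation, recalibration or decision-curve analysis is
  provided; the validation module quantifies internal optimism only.
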