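# Methods

This note documents the models implemented in `neurocrit`, the conventions
adopted where the underlying methodology leaves choices open, and what the
synthetic-data pipeline does and does not establish about real cohorts.

## Secondary-injury (Hs) classification

Ten candidate secondary brain injuries are flagged from the worst physiology
of the first 24 ICU hours: hypotension (MAP < 65 mmHg or SBP < 90 mmHg),
hypoxemia (PaO₂ < 60 mmHg or SaO₂ < 90 % or SpO₂ < 90 %), hyperthermia
(> 37.5 °C), hypercapnia (PaCO₂ > 45 mmHg or RR < 8/min), hypocapnia
(PaCO₂ < 35 mmHg), hypoglycaemia (< 60 mg/dL), hyponatremia (< 135 mmol/L),
hypothermia (< 35 °C), intracranial hypertension (ICP > 25 mmHg), and
clinical herniation.  Conventions:

- **Strict inequalities.**  A value exactly at a cutoff is negative.  The
  thresholds are printed with strict comparison operators, and equality is
  the natural boundary of "still acceptable".
- **Missing means not assessed.**  A flag requires an observed abnormal
  value; nothing is imputed.  This is conservative: unmeasured physiology
  cannot generate injuries.  A snapshot with no physiology at all yields a
  zero-flag profile plus an explicit warning rather than an error, because
  registry rows frequently lack blood-gas panels.
- **Herniation is a recorded clinical finding**, not derived from imaging
  or ICP; there is no accepted numeric rule for it.
- The flag count is categorized 0 / 1 / 2 / ≥ 3; the four categories
  partition every cohort.

## Outcome coding

mRS 4–6 is unfavourable; 0–3 favourable.  For mortality analyses the
survivor class pools ICU discharge, transfer to another hospital, and
continued hospitalization at day 30: the three dispositions sum to the
survivor denominators used by the unadjusted-OR tables, which keeps the
printed odds ratios internally consistent.  Records violating the
death ⇔ mRS 6 equivalence are rejected at validation.

## Prognostic statistics

- **2×2 odds ratios**: `OR = ad/bc`; `SE(ln OR) = √(1/a+1/b+1/c+1/d)`;
  95 % CI `exp(ln OR ± z₀.₉₇₅ SE)`; p from the Wald z.  Zero cells raise an
  error by default (none occur in the intended tables); a Haldane +0.5
  correction is available behind a flag and marked on the result.
- **Logistic regression** is fitted by IRLS/Newton–Raphson on the Bernoulli
  log-likelihood: coefficients start at 0, iteration stops when the relative
  log-likelihood change falls below 1e-10 (max 100 iterations), Wald SEs come
  from the inverse observed information at the optimum.  Separation is
  declared when any |coefficient| exceeds 30 (on these covariate scales a
  log-odds of 30 is far beyond any plausible clinical effect) and raised as
  an error rather than reported as a huge finite estimate.
- **Model suite**: four fixed specifications per outcome — (1) age, sex,
  GCS, Hs category (reference: zero), insurance, admission type;
  (2) sex, APACHE II, insurance, admission; (3) sex, SAPS III, insurance,
  admission; (4) age, sex, SOFA, insurance, admission.  Each model is fitted
  on its own complete cases; dropped-row counts are reported, mirroring the
  varying n across models when scores are missing.  In-sample ROC AUC
  (rank-based, ties counted ½) summarizes discrimination.
- **Chi-square homogeneity** uses the Pearson statistic; pairwise mode
  subsets each pair of rows (it does not re-partition the table) and
  Bonferroni-adjusts by the number of pairs.  Subsetting is the
  interpretation consistent with "two-by-two comparison" of groups.
- Wald inference everywhere; profile-likelihood intervals are deliberately
  out of scope in v1.
- Print precision is frozen at 1 decimal for percentages and 3 for ORs/CIs
  so golden-file comparisons are meaningful.

## DALY engine

`DALY = YLL + YLD`, computed from a per-patient ledger so additivity and
stratum reconciliation (by diagnosis, sex, 5-year age band, Hs category)
hold exactly rather than approximately.

- **YLL**: residual life expectancy at (sex, floor(age)) from a *complete*
  (single-year) life table; integer-age lookup needs no abridged-table
  interpolation.  Ages outside the table raise a domain error naming the
  bound.  The bundled `synthetic_life_table()` is Gompertz–Makeham with the
  level solved so e₀ matches 72.8 (male) / 79.9 (female) years — the
  structure of a national period table without being one; real tables are
  user-supplied CSVs (`sex,age,ex`).
- **YLD**: per survivor, the mRS-selected disability weight is combined with
  the patient's comorbidity weights via the multiplicative complement
  `1 − Π(1 − wᵢ)` — the standard comorbidity correction, order-invariant,
  bounded by `max(w) ≤ result ≤ Σw`.  A raw-product mode exists for
  sensitivity analysis because "multiplying the weights" is ambiguous
  between the two readings; the complement is the default as the
  convention used by burden-of-disease studies.  The result is scaled by a
  time horizon (default 1 year of prevalence, configurable down to the
  30-day follow-up, 30/365.25) and optionally by the stratum prevalence.
  Survivors with missing mRS are excluded and counted.  The bundled
  `synthetic_disability_weights()` ladder (0, 0.019, 0.070, 0.316, 0.552,
  0.588 for mRS 0–5) is shaped like published stroke-severity weights and is
  a synthetic stand-in, not an official set.
- **Prevalence**: the per-(diagnosis, sex, 5-year band) prevalent-case
  proportion is a beta-binomial posterior mean with a
  `Beta(s·p̄, s·(1−p̄))` prior shrinking toward the pooled rate p̄
  (default strength s = 10 pseudo-patients), with central 95 % posterior
  intervals; empty strata return the prior mean and are flagged.  This is a
  transparent, dependency-free substitute for Bayesian meta-regression
  tooling and is *not* equivalent to it: it borrows strength only toward the
  pooled mean, not across adjacent age bands or covariates.
- No age-weighting and no time-discounting, following current
  burden-estimation practice.

## Synthetic cohort generator

The generator emulates the structure of a multicentre neurocritical-care
cohort of 1,194 admissions in ten diagnosis groups:

- **Diagnosis mix** proportional to 317 / 218 / 211 / 155 / 91 / 77 / 70 /
  25 / 19 / 11 (elective neurosurgery, TBI, ischaemic stroke,
  encephalopathy, seizures, ICH, SAH, CNS infection, spinal cord injury,
  neuromuscular disease).
- **Ages** are truncated normal at 18 (study populations are adults) with
  group-specific means/SDs (e.g. ischaemic stroke 69.3 ± 16.9 years), floored
  to integer years; the *realized* mean of a wide-SD group therefore sits
  slightly above its location parameter.
- **Severity scores** (GCS, APACHE II, SAPS III, SOFA) and length of stay
  are drawn from piecewise-linear quantile functions through the
  group-specific (q1, median, q3) with Tukey-fence tails, rounded to the
  integer lattice.  Published summaries give only medians and IQRs; this
  family is a declared convention, not an inference about the real data.
- **Hs burden**: a per-group category (0/1/2/≥3) is drawn first (≥3 expands
  to counts 3–6 with probabilities 0.60/0.25/0.10/0.05); the member flags are
  then sampled without replacement with Gumbel-top-k weights equal to the
  marginal flag prevalences, with hyperthermia/hypothermia mutually
  exclusive (one body temperature).  Physiology is then drawn inside
  flag-consistent intervals, so the classifier reproduces the generated flag
  set for every patient — an invariant, re-checked at record validation.
- **Outcome model**: death is Bernoulli with logit linear in age, male sex,
  GCS, Hs category, public insurance and emergency admission.  Default
  log-odds use adjusted-OR-sized effects (e.g. emergency 5.77, ≥3 Hs 8.663)
  as realistic settings; the intercept (−4.7166) is calibrated once against
  the generator's own covariate distribution to give 15.7 % marginal ICU
  mortality.  Survivor mRS comes from an ordinal-logistic allocation on the
  unfavourable-outcome linear predictor with cutpoints (−0.2746, 0.8349,
  1.473, 2.0478, 3.2185) calibrated once to the reference survivor mRS
  margins (283/201/121/100/154/140).  Matching those margins is a
  calibration goal, not an invariant.  Missingness of SAPS III, SOFA and
  survivor mRS is Bernoulli at the reference rates (35/1194, 54/1194,
  7/1006).
- **Reproducibility**: every variable has its own counter-based Philox
  stream keyed by (seed, variable name) and consumes exactly one draw per
  patient, so identical specs give identical cohorts and growing
  `n_patients` never perturbs earlier patients.

**What passing tests do and do not show.**  The generator produces the right
marginals, group structure and a correctly specified outcome model, so
parameter-recovery and calibration results demonstrate the *estimators* are
sound (type-I error 5 % ± 1 %, CI coverage ≥ 90 %).  It does not emulate
between-site heterogeneity, seasonal effects, longitudinal physiology,
within-group correlation between severity scores and outcome beyond the
group level, or informative missingness — so pipeline performance on real
registries (e.g. AUCs of the score-based models) is not established by these
tests.

## Problem sizes

Marginal-fidelity checks run at n = 50,000 (binomial noise ≈ 0.2 pp);
parameter recovery at n = 20,000 with 100 replicates; type-I error with
2,000 replicates of n = 500; null-AUC at n = 10,000; classifier/oracle
agreement on 10,000 random snapshots.  These sizes put Monte-Carlo noise an
order of magnitude below each asserted tolerance while keeping the full
suite under a minute.

## Known limitations

- The severity-score distributions within groups are independent of the
  outcome given the group, so models 2–4 discriminate less on synthetic data
  than they would on real data.
- The beta-binomial prevalence stand-in ignores spatial/temporal structure
  and remission, and its intervals are conditional on the observed cohort.
- The YLD horizon of a 30-day cohort is genuinely ambiguous; it is exposed
  as a parameter rather than fixed.
- Comorbidities are drawn independently of age and of each other, which
  understates real-world clustering.
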