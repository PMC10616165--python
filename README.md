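# neurocrit

Analysis toolkit for **neurocritical-care cohort studies**: patients admitted
to intensive care for an acute neurological disorder (stroke, traumatic brain
injury, encephalopathy, …), followed for 30 days for vital status and
functional outcome on the modified Rankin Scale (mRS).

The package covers the full analysis chain of such a study:

1. **Secondary-injury ("Hs") classification** — ten threshold rules on
   admission physiology (hypotension MAP < 65 mmHg or SBP < 90 mmHg,
   hypoxemia PaO₂ < 60 mmHg or SaO₂/SpO₂ < 90 %, hyperthermia > 37.5 °C,
   hypercapnia PaCO₂ > 45 mmHg or RR < 8/min, hypocapnia PaCO₂ < 35 mmHg,
   hypoglycaemia < 60 mg/dL, hyponatremia < 135 mmol/L, hypothermia < 35 °C,
   intracranial hypertension ICP > 25 mmHg, clinical herniation).  All
   inequalities are strict; missing measurements never fire a flag.  The
   count is categorized as 0 / 1 / 2 / ≥ 3.
2. **Outcome coding** — ICU death vs survival, and the mRS dichotomy
   (4–6 unfavourable, 0–3 favourable).
3. **Prognostic models** — unadjusted 2×2 odds ratios
   `OR = ad/bc` with Wald intervals
   `exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))`, logistic regression fitted by
   IRLS (Newton–Raphson) with Wald inference, four fixed multivariate
   specifications (GCS + Hs model; APACHE II; SAPS III; SOFA — each with sex,
   insurance and admission type), rank-based (Mann–Whitney) ROC AUC, and
   chi-square homogeneity tests with Bonferroni pairwise comparisons.
   Complete-case analysis throughout; dropped rows are counted, never imputed.
4. **Disease burden** — DALY = YLL + YLD.  Each death contributes the
   residual life expectancy e(age, sex) from a complete life table; each
   survivor contributes a disability weight selected by mRS, corrected for
   comorbidities with the multiplicative complement `1 − Π(1 − wᵢ)`, scaled
   by a time horizon and optionally by stratified prevalence (a transparent
   beta-binomial shrinkage estimator per sex × 5-year age band).
5. **Synthetic cohorts** — a fully configurable generator that reproduces the
   structure of such a cohort (ten-group diagnosis mix, group-wise
   age/sex/severity distributions, Hs burden with physiology that classifies
   back to the generated flags, and a logistic outcome model with
   configurable odds ratios), so the whole pipeline is testable without any
   patient data.

## Worked example

```python
import neurocrit as nc

# classify one admission's worst first-24h physiology
snap = nc.PhysiologySnapshot(map_mmHg=58.0, sbp_mmHg=85.0, temp_C=38.4,
                             paco2_mmHg=33.0, glucose_mg_dL=104.0,
                             sodium_mmol_L=138.0, icp_mmHg=12.0)
profile = nc.classify_hs(snap)
print(sorted(profile.flags), profile.count, profile.category)
# ['hyperthermia', 'hypocapnia', 'hypotension'] 3 three_plus

# unadjusted mortality OR for >=3 secondary injuries vs none
t = nc.TwoByTwo(exposed_events=82, exposed_nonevents=91,
                ref_events=22, ref_nonevents=478)
res = nc.odds_ratio(t)
print(f"OR {res.or_point:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
# OR 19.578 (95% CI 11.625-32.973)

# synthetic cohort -> multivariate mortality model -> DALY accounting
frame = nc.generate_frame(nc.CohortSpec(n_patients=1194, seed=7))
spec1 = next(s for s in nc.MODEL_SPECS
             if s.name == "model1_gcs_hs" and s.outcome == "mortality")
fit = nc.run_model(frame, spec1)
print(fit.table.loc[["gcs", "hs_three_plus", "emergency"],
                    ["or_", "ci_low", "ci_high"]].round(3))
#                  or_  ci_low  ci_high
# gcs            0.884   0.849    0.921
# hs_three_plus  8.866   5.344   14.710
# emergency      6.968   3.958   12.268
print(f"n_used={fit.n_used}, AUC={fit.auc:.3f}")
# n_used=1194, AUC=0.818

burden = nc.compute_dalys(frame, nc.synthetic_life_table(),
                          nc.synthetic_disability_weights(),
                          prev=nc.estimate_prevalence(frame))
print(f"YLL={burden.yll_total:.1f}  YLD={burden.yld_total:.1f}  "
      f"DALY={burden.daly_total:.1f}")
# YLL=3833.0  YLD=52.2  DALY=3885.2
```

Reading the numbers: patients with three or more secondary injuries at
admission have ~20-fold the odds of ICU death of patients with none; in the
synthetic cohort the fitted model recovers the configured effects (each GCS
point lowers the odds of death ~12 %), discriminates with AUC ≈ 0.82, and
nearly all of the ~3,900 healthy life-years lost come from premature
mortality (YLL), with traumatic brain injury the costliest diagnosis.

A command-line interface mirrors the library:

```bash
neurocrit simulate --n 1194 --seed 7 --out cohort.csv
neurocrit classify-hs --cohort cohort.csv --out hs.csv
neurocrit fit --cohort cohort.csv --model model1_gcs_hs --outcome mortality --out fit.csv
neurocrit daly --cohort cohort.csv --out daly.json
neurocrit report --cohort cohort.csv --out-dir report/
```

## Layout

- `src/neurocrit/cohort.py` — domain types, validation, Hs classifier, outcome coding
- `src/neurocrit/io.py` — cohort CSV schema and round-trip I/O
- `src/neurocrit/simulate.py` — synthetic cohort generator
- `src/neurocrit/stats.py` — odds ratios, IRLS logistic regression, AUC, chi-square
- `src/neurocrit/models.py` — the four multivariate specifications and suite runner
- `src/neurocrit/burden.py` — life tables, disability weights, prevalence, DALYs
- `src/neurocrit/report.py`, `src/neurocrit/cli.py` — report tables and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
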