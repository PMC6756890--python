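# cogload

Lifestyle, physiology and cognition in late middle age: a tested, reusable
implementation of a composite-score + regression pipeline used in cognitive
aging epidemiology, together with a synthetic-cohort generator so every stage
is verifiable without access to participant data.

The pipeline quantifies, for each participant aged 50–69:

* **PACC5** — the Preclinical Alzheimer Cognitive Composite, the sum of the
  z-scores of five neuropsychological measures (FCSRT free + total recall,
  Logical Memory delayed recall, Digit Symbol Substitution, animal fluency,
  Mattis Dementia Rating Scale);
* **Cognitive reserve (CR)** — a z-composite of education years, fNART
  (crystallized intelligence), an occupation score
  `Occupation = Σᵢ cᵢ·hᵢ·yᵢ` (cognitive load × weekly hours × years per
  job), lifetime physical activity `P = Σᵢ METᵢ·tᵢ` averaged over four life
  periods, and a leisure score `Lᵢ = Σᵢ fᵢ·tᵢ·pᵢ` averaged over nine
  activities;
* **Allostatic load (AL)** — the z-score of the average of seven subdomain
  z-composites (cardiovascular, parasympathetic, lipid, glucose,
  inflammation, HPA axis, sympathetic) built from 18 biomarkers, with the
  protective measures HDL, DHEA-S, SDANN and RMSSD sign-reversed and urinary
  analytes corrected for serum creatinine;
* **Affective state** — z-composite of BDI and BAI;
* **Sleep-wake quality** — z-composite of PSQI, ESS and the actigraphic
  **intradaily variability** `IV = c¹ʰ/d¹ʰ`, where `c¹ʰ` is the mean squared
  hour-to-hour change in active minutes and `d¹ʰ` the population variance of
  the hourly totals (after masking >120-min zero-count gaps, binarizing
  1-min epochs at ≥4 counts, and hourly clustering).

The inference stage reproduces the study's statistical sequence: a ±3 SD
outlier pass per model, per-subject linear models (the collapsed form of a
subject-intercept mixed model, whose Kenward-Roger denominator df is
`n − p − 1` here), Wald F tests with semi-partial `R²β = (qF/ν)/(1+qF/ν)`,
TOL/VIF collinearity diagnostics, BIC screening of interaction terms, summary
t-tests by sex, and a G*Power-style sensitivity analysis for the minimal
detectable effect of a single regression coefficient.

## Worked example

```python
from cogload import make_config
from cogload.synthetic import generate_cohort
from cogload.scoring import score_cohort
from cogload.inference import run_model_sequence, sensitivity_minimum_effect

cfg = make_config(n_participants=81, seed=7)      # default study conditions
scored, _ = score_cohort(generate_cohort(cfg))
report = run_model_sequence(scored)

fit = report.models["global_cr"]
print(f"global reserve model: n = {fit.n_used}, removed = {list(fit.removed_ids)}")
print(fit.terms[["estimate", "se", "F", "df_den", "p"]].round(4))
print("significant global factors:", report.significant_global)
print("significant sub-factors:  ", report.significant_sub)

sens = sensitivity_minimum_effect(n=81)
print(f"minimal detectable effect: f2 = {sens.f2:.4f} (f = {sens.f:.2f}, exact r = {sens.r:.2f})")
```

prints

```
global reserve model: n = 81, removed = []
           estimate      se       F  df_den       p
sex         -1.7665  1.0139  3.0352      77  0.0855
age         -0.5450  0.5017  1.1802      77  0.2807
cr_global    1.0390  0.4986  4.3430      77  0.0405
significant global factors: ('cr_global',)
significant sub-factors:   ('al_lipid', 'al_symp')
minimal detectable effect: f2 = 0.0777 (f = 0.28, exact r = 0.27)
```

At the default simulated conditions (n = 81, reserve effect +0.3, load effect
−0.2 on latent cognition), the cohort shows a significant positive reserve
association with PACC5 (estimate on the raw PACC5 scale, whose SD is ≈ 4.5),
and the lipid-metabolism and sympathetic subdomains of allostatic load emerge
in the sub-factor models — the qualitative pattern such cohorts are designed
to exhibit. The sensitivity line says a single-coefficient effect of
f² ≈ 0.08 (f ≈ 0.28) is the smallest detectable with power .8 at α = .05
one-tailed with 81 subjects and three predictors.

The same stages are available from a shell:

```bash
cogload simulate --n 81 --seed 7 --out cohort.csv
cogload score --cohort cohort.csv --out scored.csv
cogload fit --cohort scored.csv --out models/
cogload iv --epochs epochs.csv --threshold 4 --max-gap 120
cogload power --n 81
cogload report --seed 7 --out report/        # end-to-end with manifest
```

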