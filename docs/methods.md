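# Methods

## Scope and model

`cogload` implements a cross-sectional analysis linking cognitive
performance in late middle age (ages 50–69) to four factor families —
cognitive reserve, affective state, allostatic load and sleep-wake quality —
through composite scores and a staged regression sequence. Because no
participant-level data are available, the package ships a synthetic-cohort
generator whose defaults encode the study conditions (n = 81, 66.7 % women,
published per-measure means/SDs/ranges); all statistical machinery is
validated against that generator plus closed-form and printed quantities.

## Composite scoring

All composites use one aggregation primitive: standardize each constituent
(z-score), multiply by a direction sign, average within participant,
re-standardize the averages over the cohort. Consequences asserted by test:
every global composite has cohort mean 0 and SD 1 (tolerance 1e−9), and is
permutation-equivariant and deterministic.

Conventions:

* **SD convention.** Sample SD (n−1 denominator) estimated on the analysis
  cohort. `ZReference` is injectable so external norms can replace
  cohort-estimated moments.
* **PACC5** is the *sum* (not mean) of the five test z-scores; its SD is
  therefore ≈ 4.5 under the default conditions, and raw-scale regression
  estimates on PACC5 are comparable to published magnitudes.
* **Allostatic load** aggregates 7 subdomain composites; HDL, DHEA-S, SDANN
  and RMSSD enter with sign −1 so that higher always means higher load.
  Urinary cortisol, adrenaline and noradrenaline are divided by serum
  creatinine (a simple ratio; no exponent) as the lean-body-mass adjustment.
* **Occupational cognitive load** `c` is accepted as a supplied ordinal 1–9
  (higher = more demanding), as an ISCO-major-group-derived rating would be;
  the mapping itself is the caller's input, not hard-coded.
* **Leisure encoding**: `f` = events per interval, `t` = intervals per year
  (weekly → 52, monthly → 12, daily → 365), `p` = years; activities never
  practiced score 0; the global score averages the nine activities.
* **Physical activity**: per life period, sum of MET × weekly hours over
  that period's activities; the global score is the mean over the four
  periods (empty periods contribute 0).
* **fNART** enters as its raw total score; no error-to-IQ conversion.
* **SDANN vs SDNN.** On a single 5-min recording, the SD of 5-min segment
  means is undefined (one segment), so `sdann` degenerates to the SD of the
  beat intervals (SDNN). Both functions are exposed; which one the original
  ECG software reported is not determinable from a 5-min protocol.

## Intradaily variability

Fixed pipeline order: mask → binarize → hourly cluster → IV.

* Masking targets runs of **zero raw counts** strictly longer than 120 min
  (a device-off proxy), applied before binarization so genuine low activity
  is not masked. The boundary is strict: a 120-min run survives.
* Binarization is inclusive: count ≥ 4 is active. Threshold and gap are
  configurable.
* Hours are aligned to recording start (not clock hours); an hour containing
  any masked epoch is dropped whole, and its position is recorded.
* `IV = c¹ʰ/d¹ʰ` with `d¹ʰ` the population variance (denominator n) and
  `c¹ʰ` the mean squared difference over *temporally adjacent retained*
  hour pairs — differences spanning a dropped hour are excluded, avoiding
  spurious fragmentation at gap edges. Degenerate inputs (constant hourly
  series, <2 hours, no adjacent pairs) raise typed errors.

Reference behaviours (tested): a 0/60 alternating hourly series gives
exactly c¹ʰ = 3600, d¹ʰ = 900, IV = 4; an i.i.d. hourly series gives IV → 2;
IV ≤ 4n/(n−1) for any bounded series.

## Synthetic cohort

A latent-trait Gaussian copula. Per participant: independent standard-normal
traits (true reserve CR*, true load AL*, affective, sleep) plus an age
latent and a 0/1 sex code (0 = female — published sex estimates are then
negative, matching the reported female advantage). Latent cognition is

    C = b_cr·CR* + b_al·AL* + b_sex·sex + b_age·z_age + ε,  ε ~ N(0, noise_sd²)

with defaults b_cr = +0.3, b_al = −0.2, b_sex = −0.5, b_age = −0.1,
noise_sd = 0.9 (making Var(C) ≈ 1, so the b's read as standardized slopes).
The magnitudes correspond to the published standardized effect pattern
(reserve ≈ +0.2…0.3, load ≈ −0.2, a ≈ 0.5 SD female advantage).

Every raw measure is a monotone quantile map of
`loading·trait + √(1−loading²)·noise` onto a bounded marginal solved to
match the published (mean, SD, min, max): a truncated normal where feasible,
otherwise a min-shifted (or max-mirrored) truncated lognormal for strongly
skewed measures (CRP, IL-6, triglycerides, SDANN, RMSSD, BDI, BAI; the
dementia scale is ceiling-compressed and uses the mirrored family). Solved
maps reproduce published moments essentially exactly and respect printed
ranges by construction. One deliberate documented discrepancy is inherited
from the source tables: the BMI marginal runs to the printed maximum 30.12
even though the recruitment criteria state BMI ≤ 29.

Loadings (tests 0.90 on C, reserve sub-scores 0.85 on CR*, biomarkers 0.70
on AL*, BDI/BAI 0.75, sleep measures 0.60) are deliberately high: they make
the scored composites near-faithful proxies of the latent traits so that
injected effects are recoverable within ±0.1 at n = 1000 — the calibration
the test suite asserts. Real biomarker panels inter-correlate far more
weakly; passing tests therefore demonstrate correctness of the machinery
under idealized measurement, not expected precision on real data. Likewise
the PACC5 tests carry small test-specific noise (a strictly noise-free
monotone map would make the five tests rank-identical). Affective and sleep
traits have no effect on cognition by default, mirroring the null published
associations. Serum creatinine (no published marginal) uses a typical adult
reference range: mean 0.85, SD 0.13, range 0.5–1.3 mg/dL. Questionnaire and
test scores are generated as continuous values; integer rounding is not
applied.

`generate_cohort(..., with_histories=True)` additionally materializes
episode-level lifestyle histories (jobs, sport episodes per life period,
nine leisure activity slots) whose scores reproduce the table's occupation /
sport / leisure columns exactly; episode splits are randomized and not
constrained to be biographically consistent (e.g. total years may exceed a
working life) — they exist to exercise the scoring formulas.

The actigraphy generator is a two-state minute-level Markov process with a
24-h sinusoidal drive (preferred active period ≈ 07:00–19:00); the
fragmentation parameter adds to both switch hazards. Rest minutes emit
occasional small nonzero counts (8 % of minutes), so only unusually long
quiet stretches trigger the device-off mask. `fragmentation = 0` is the
deterministic limit: strict 12-h alternation with rest counts of 1, keeping
IV defined. Mean IV rises monotonically in fragmentation (Spearman ρ ≈ .99
over 20 levels × 20 seeds). The RR-interval generator is an AR(1) (φ = 0.9)
whose innovation SD is set so the expected RMSSD equals the requested
short-term SD.

Reproducibility: all generators consume a single integer seed through
`numpy.random.SeedSequence`; identical (config, seed) reproduce outputs
byte-for-byte, and the pipeline fans one seed into per-stage child seeds.

## Inference

* **Model form.** One observation per subject makes a subject-intercept
  variance component unidentifiable, and the GLS fixed effects equal OLS for
  any value of that variance; models are fitted as OLS, and a MixedLM
  cross-check asserts equality of fixed effects to 1e−8. The Kenward-Roger
  denominator df in this design is the residual df `ν = n − p − 1`, which
  reproduces every published (n, df) pair.
* **Outcome distribution.** Gaussian with identity link (PACC5 is a z-sum);
  no model-family search is performed.
* **Outlier screening** is per model: listwise deletion of missing rows
  first, then a single pass removing rows strictly outside mean ± 3 SD on
  any variable entering the model (outcome + continuous predictors,
  including age; thresholds from pre-removal moments). This per-model
  screening is why the analysed n varies across models.
* **Standardization.** Continuous predictors are z-scored on the
  post-screening analysis sample; sex stays 0/1. Age estimates are therefore
  per-SD, which the report header notes. For parameter-recovery checks the
  outcome can be standardized too (`standardize_outcome=True`), putting
  slopes on the latent standardized scale.
* **Per-term tests.** Wald F = (estimate/SE)² on (1, ν); semi-partial
  `R²β = (qF/ν)/(1+qF/ν)` is attached to terms with p < .05, matching the
  published tables' convention. p-values are written to 4 decimals and R²β
  to 2 in report files.
* **Model sequence.** Four global-factor models → four sub-factor models →
  combined models carrying forward terms significant at p < .05 (for globals
  and for sub-scores separately); with nothing significant, a
  covariates-only model is reported with an explanatory note.
* **Interactions** are screened by BIC: the main-effects model vs the model
  adding all pairwise products of standardized focal predictors; lower BIC
  wins. Simulations (tested) prefer main effects ≥ 90 % of seeds under a
  no-interaction truth at n = 500, and the interaction model under a strong
  (0.5 SD) interaction.
* **Summary t-tests.** `welch_ttest` gives Welch (default) or pooled tests
  from summary statistics. `ttest_summary` additionally implements the
  classical folded-F selection (pooled when an equality-of-variance test is
  non-significant at .05, Welch otherwise) — the convention of mainstream
  commercial packages, and the only one that reproduces *all* published
  sex-comparison p-values: the age and education rows match the pooled test,
  the depression and anxiety rows (variance ratios ≈ 2.3) match Welch.
* **Sensitivity analysis.** The minimal detectable f² for a single
  coefficient solves `power = P(T(ν, √(f²·n)) > t₁₋α)` with ν = n − p − 1
  (noncentrality convention λ = f²·n; λ = f²·(ν+1) is available as an
  option). At n = 81, α = .05 one-tailed, power .8, p = 3 this gives
  f² = .0777. The result reports both Cohen's f = √f² = .28 — the scale on
  which such minima are conventionally quoted, since f² ≈ R² for small
  effects (.0777 → ".08") — and the exact conversion r = √(f²/(1+f²)) = .27.
  The Monte-Carlo replay uses a *fixed* orthogonalized design (focal column
  sum of squares = n), under which the noncentral-t model is exact; with
  random designs the same f² yields power ≈ .78, because the realized
  partialled sum of squares averages n − p rather than n.

## Problem sizes and numerical choices

Simulation-based checks run at the sizes their claims name: parameter
recovery uses 50 cohorts of n = 1000; type-I calibration uses 2000 cohorts
of n = 81; the power replay uses 10⁵ replicates; IV monotonicity uses 20
fragmentation levels × 20 seeds × 14 days. The whole suite completes in a
few minutes on one core.

Ties and degeneracies are typed errors, not silent results: zero-variance
measures (composite scoring), constant hourly series (IV), singular designs
(model fit), zero-SD pairs (t-tests), unattainable power (sensitivity).
Marginal solving uses least squares on (μ, log σ) with closed-form moments,
accepts a family at relative moment error ≤ 0.5 %, and refuses marginals no
bounded family can reach (error > 10 %).

## Limitations

* The generator's high loadings and independent latent traits are idealized;
  it does not emulate reserve-load correlation, item-level questionnaire
  structure, missingness mechanisms, or biographically consistent lifestyle
  histories.
* The published headline regression estimates are not recomputable without
  the original data; the package reproduces the derived quantities that are
  (effect sizes from printed F/df, df accounting, t-test p-values, the
  sensitivity analysis) and validates everything else behaviourally.
* Only Gaussian outcomes and one-row-per-subject designs are supported; no
  general Kenward-Roger machinery, no multiple-testing correction (the
  original analysis applied none), no interdaily-stability/cosinor
  actigraphy metrics, and no vendor file formats.
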