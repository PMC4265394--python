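# Methods

## Model structure

The risk engine is a cause-specific proportional-hazards model on a
discrete annual grid. For patient *i* in ER stratum *s*, the annual
breast-cancer hazard in year *t* (years 1..H, default horizon H = 10) is

    h_bc(i, t) = h0_s(t) · RH_i · τ_i

with `h0_s(t)` the baseline annual hazard of the reference-category
patient, `RH_i` the patient's relative hazard and `τ_i` the product of
the hazard multipliers for the patient's adjuvant therapies. `RH_i` is

    RH_i = HRnode^c_node · HRsize^c_size · HRgrade^c_grade
           · HRscreen^[screen-detected] · m_HER2 · m_KI67

where the `c` are ordinal category codes: nodes (0, 1, 2–4, 5–9, 10+ →
0..4), size in mm (<10, 10–19, 20–29, 30–49, 50+ → 0..4), grade (1/2/3 →
0/1/2). Mean imputation can make a code fractional, in which case the
hazard ratio is raised to the fractional exponent — the geometric
interpolation consistent with a log-linear Cox model.

### Marker terms and mean-one renormalization

A binary marker with positive:negative hazard ratio `r` and positivity
prevalence `p` contributes `h_neg` to negatives and `h_pos` to
positives, defined by the two constraints `h_pos = r·h_neg` and
`p·h_pos + (1−p)·h_neg = 1`, i.e. `h_neg = 1/(1−p+p·r)`. The second
constraint (prevalence-weighted average relative hazard of one) ensures
that adding the marker does not shift the cohort-average hazard, so the
baseline hazards fitted without the marker remain valid. With `r = 1.3`,
`p = 0.412` this gives 0.890/1.157 for KI67 (0.89/1.16 at two decimals);
`p = 0.412` is the value implied by inverting the renormalization from
that printed pair, and ships as the default. A fractional (imputed)
marker status `m` contributes the mixture `(1−m)·h_neg + m·h_pos`; a
fully missing status contributes exactly 1, the cohort-average term.
The KI67 term enters only in model version v3 and only for ER+ patients
(KI67 carries no prognostic signal in ER− disease in this model family);
the HER2 term enters in both versions. v2 and v3 are therefore
identical for every ER− patient — an invariant the test suite enforces.

### Competing risks

Other-cause mortality uses an age-indexed annual hazard (life table) at
the patient's attained age. Within each year, total deaths
`S(t−1)·(1−exp(−(h_bc+h_oc)))` are split between causes in proportion to
their hazards. For piecewise-constant hazards this proportional split
equals the exact continuous-time cause-specific cumulative incidence
`∫ S(u)·h_bc(u) du`, so the discretisation introduces no bias, and the
three-way accounting `overall survival + cuminc_bc + cuminc_oc = 1`
holds to machine precision at every year.

### Treatment benefit

For each option (endocrine, chemo, both — "both" multiplies the two
hazard ratios) the curves are recomputed with the multiplier applied to
the breast-cancer hazard only; the benefit is the difference in overall
survival against the untreated curves at 5 and 10 years.

## Parameters and defaults

Published per-unit hazard ratios: nodes 1.75/1.55, size 1.43/1.44,
grade 2.33/1.50, screen detection 0.70/0.86 (ER+/ER−); KI67 HR 1.3 at
prevalence 0.412. The remaining parameters are **synthetic plausible
defaults**, clearly not published coefficients:

- `baseline_annual_hazard` — ER+ rising from 0.0014 to 0.0044/yr
  (10-year cumulative 0.035); ER− peaking in years 2–3 at 0.021–0.024/yr
  (cumulative 0.126). Shapes are conventional for breast-cancer annual
  hazards (ER− risk is front-loaded); levels were set once so that a
  default simulated cohort reproduces the validation cohort's 10-year
  cause-specific death fractions (~17% ER+, ~31% ER−) and then frozen.
- `her2` — HR 2.0 at prevalence 0.10, a placeholder of realistic
  magnitude for HER2 positivity in the pre-trastuzumab era.
- `treatment` — hazard multipliers 0.71 (endocrine) and 0.78
  (first-generation chemotherapy), in the range reported by the adjuvant
  therapy meta-analytic literature.
- `life_table` — Gompertz-shaped female all-cause hazard
  `exp(−10.6 + 0.095·age)` for ages 25–100 (≈0.003 at 50, ≈0.02 at 70).

All of these are configurable through a YAML/JSON `ModelConfig` file.

## Cohort handling

- **Staging exclusion**: node-negative records with fewer than four
  nodes sampled are removed (an unreliable node-negative call); records
  with missing staging fields are retained, and node-positive records
  are retained regardless of sampling adequacy. The operation is
  idempotent.
- **Mean imputation** replaces missing size by the cohort mean (mm),
  missing grade by the mean ordinal code, missing HER2/KI67 by the
  observed positivity proportion, and a missing nodal count by the mean
  node-*category* code. Cohort means are used (rather than external
  reference values) and recorded in the imputation log. Binary-marker
  means are deliberately fractional: the engine consumes them as
  prevalence weights, which is the hazard-scale analogue of "mean of a
  0/1 coding".

## Validation metrics

- **Outcome classification at the horizon**: breast-cancer death at or
  before the horizon is an event; other-cause death before the horizon
  is a non-event for the cause-specific endpoint (flagged distinctly);
  censoring before the horizon leaves the status unknown. ROC analyses
  exclude the unknown-status patients and report how many were dropped;
  this exclude-censored policy is the package default and the only one
  implemented.
- **Calibration**: expected deaths are sums of predicted cumulative
  breast-cancer mortality over stratum members; observed counts get
  exact (Garwood) Poisson 95% intervals, the standard choice for
  observed/expected death counts. Strata are clinical-characteristic
  bands (age, size, nodes, grade, HER2) or quantiles of predicted risk;
  quantile binning breaks ties by a stable sort on (value, id) so bins
  are reproducible. Any number of quantile bins is supported; the
  default is quintiles.
- **Goodness of fit**: `χ² = Σ (O−E)²/E` over the quantile bins with an
  upper-tail p-value at df = k by default (the 5-d.f. convention for
  quintiles); df is configurable (k−1 and k−2 are common alternatives)
  and always reported.
- **AUC**: the Mann–Whitney estimator with the half-tie kernel,
  implemented through midranks; its variance and the v2-vs-v3
  comparison use DeLong's placement-value (structural-component)
  method, which accounts for the pairing of the two score vectors on
  the same patients. Degenerate cases (zero variance) return p = 1 with
  a flag rather than dividing by zero.

## Synthetic cohorts

The generator emulates a 1990s hospital-registry validation cohort:
covariate category probabilities default to the published ER+ margins of
that cohort (e.g. ER+ fraction 1274/1726, grade 3 in 395/1158 graded
cases), missingness is masked on per-variable at the published rates
(HER2 405/1274; the KI67 rate is not published and is set equal to the
HER2 rate as a documented assumption), and outcomes are drawn from the
same piecewise-exponential hazard model the engine predicts with:
breast-cancer times by inverse-transform sampling of the individual
annual hazards, other-cause times from the life table, exponential
random censoring (default 0.005/yr — death ascertainment through
national registry linkage loses very few patients) truncated at an
administrative horizon of 15 years. Outcomes are generated from the
complete covariates *before* missingness is applied, mirroring the
real-world process and allowing imputation-degradation studies.

What the generator does **not** emulate: correlations between
covariates (KI67 and grade are strongly associated in real tumours;
here all covariates are drawn independently), non-proportional hazards,
informative censoring, or measurement error in markers. Passing tests
therefore show internal consistency of engine + simulator and
correctness of the statistical machinery — not real-world transportability.
Because KI67 is independent of the other covariates, its incremental
discrimination value here is an upper bound for a given hazard ratio.

### Experiments

- **Parameter recovery**: replicate cohorts (default n = 5,000, 20
  replicates) are fitted with a cause-specific Cox regression
  (other-cause deaths censored) on the engine's category codes in the
  ER+ stratum; the summary reports each coefficient's mean estimate and
  Monte-Carlo standard error against the generator's log hazard ratio.
- **Discrimination gain**: replicate cohorts with a chosen true KI67
  hazard ratio are scored by v2 and v3 (prediction config fixed at the
  default, KI67 HR 1.3) and compared by DeLong's test in the ER+ subset
  with complete markers. With a truly prognostic marker (HR 1.3) the
  mean AUC difference is positive but small — the population value
  implied by HR 1.3 at prevalence 0.412 is ≈0.003, so the per-replicate
  DeLong z at n = 5,000 averages ≈1.7 and the test rejects in roughly
  half the replicates rather than reliably; with a null marker (HR 1.0)
  the difference centres near zero (slightly negative, since the v3
  term is then pure noise). The acceptance script reports the measured
  mean gain and rejection fraction.

## Numerical and design choices

- Annual discrete grid throughout: it matches the life-table structure
  and keeps every quantity closed-form testable.
- Age enters only through the other-cause life table; the breast-cancer
  hazard has no age term (none is published for this model family's
  per-unit codes). A config hook (`life_table`, per-ER parameters)
  permits extension without code change.
- Missing detection mode multiplies the hazard by 1 (neither screening
  benefit nor penalty).
- Baseline arrays shorter than the requested horizon raise an error in
  prediction; the simulator extends the baseline at its final value
  beyond the configured years, since follow-up runs past the prediction
  horizon.
- Problem sizes for the simulation studies (20 replicates at n = 5,000;
  self-consistency at n = 10,000) were chosen to give Monte-Carlo
  standard errors comfortably below the effects being measured.
- Tolerances: renormalization identities hold to 1e-12; competing-risk
  conservation to 1e-9; AUC equals exhaustive pair enumeration to 1e-12.

## Known limitations

- The shipped baseline hazards, HER2 parameters, treatment multipliers
  and life table are synthetic stand-ins; predictions from the default
  config are structurally realistic but not clinically usable numbers.
- Only the exclude-censored ROC policy is implemented (inverse
  probability of censoring weighting would be the natural extension).
- Mean imputation is the only missing-data strategy, by design; no
  multiple imputation or missingness-mechanism modelling.
- The discrete annual grid ignores within-year covariate changes (e.g.
  therapy starting mid-year).
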