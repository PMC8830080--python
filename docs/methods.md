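# Methods

## The cost model

Each of the five modelled hospital-cost categories (disposable supplies,
drugs, operation-related, laboratory tests, other) follows a generalized
linear model with gamma errors and a log link:

    E[cost_c | x] = exp(b0_c + x' b_c)

Positive, right-skewed cost data are the canonical use case for this family;
the log link makes every coefficient a multiplicative effect on cost, which
is what the decision model needs (the powered-stapler scenario scales each
category by `exp(beta_stapler,c)`). Fitting is maximum likelihood via IRLS
(statsmodels), with:

* convergence at relative deviance change < 1e-8, at most 100 iterations
  (non-convergence raises, it is never returned silently; an exactly perfect
  fit — our noise-free oracle data — is accepted as converged);
* dispersion estimated by the Pearson statistic / residual degrees of
  freedom;
* Wald 95% CIs and p-values from the observed information (normal
  quantiles);
* a constant intercept-only response handled in closed form
  (`intercept = log(mean)`, zero-width CI), where IRLS cannot start.

A log-normal alternative (OLS on log cost, geometric-mean predictions) is
available via `family="lognormal"` as a sensitivity analysis.

Model selection mirrors standard cost-study practice: a univariable screen
per category (default alpha 0.05, two-sided) decides which covariates enter
the multivariable fit; the stapler-type indicator is forced into every
equation regardless of screening because it is the decision variable. BMI
bands are coded as one-vs-rest 0/1 indicators against "all other bands"
(boundaries 18.5, 24, 28, 30, 40 kg/m², half-open `[lo, hi)`), matching how
the reference coefficient table phrases them, not as levels of one factor.

When a coefficient table is consumed from published values rather than
fitted, the standard error of a term is derived from its 95% CI as
`(upper - lower) / 3.92`, assuming normality on the log scale.

## The decision model

Seven categories are costed per scenario. Device acquisition is
`mean devices per episode x unit price`; the five modelled categories come
from the cost equations. Two modes:

* **aggregate_calibrated** (default): the manual scenario's per-category
  baseline costs are taken as calibration inputs; the powered scenario
  multiplies each by `exp(beta_stapler,c)`. This runs from published
  aggregate values alone.
* **patient_level**: per-patient predictions `exp(x'b)` with the stapler
  indicator forced to each arm, averaged over a cohort. The two modes agree
  exactly whenever the cohort's mean manual-arm category costs equal the
  calibration values (tested).

The shipped device means are back-solved from the published acquisition
cells (e.g. manual staplers 4790/3970 = 1.20655 per episode, cartridges
18308/2441 = 7.50020) because the unrounded utilization means behind the
published table are not printed; the rounded means (1.2, 7.5) are what the
synthetic generator draws around. The Victor Medical scenario defaults to
the published acquisition cells (stapler ¥4,882, cartridge ¥20,974), which
are *not* equal to Victor unit prices x manual utilization (that arithmetic
gives ¥4,585 / ¥22,404); both routes are exposed and the discrepancy — an
inconsistency internal to the published aggregate inputs — is covered by a
test rather than resolved.

The published comparison table is printed in whole yuan and is internally
inconsistent by a few CNY per cell (its powered column does not exactly
equal its manual column times `exp(beta)`), so recomputed totals match the
printed ones to within a few CNY, not exactly; the engine keeps full
precision internally and rounds only at the reporting layer.

### One-way sensitivity (tornado)

Each category's stapler coefficient is varied across its 95% CI, and each
unit price by ±20% (configurable), one parameter at a time with everything
else at base case. Entries are ranked by the induced swing in the total
difference and always bracket the base case.

### Probabilistic sensitivity analysis

Per iteration, every simulated patient in the n=388 model cohort receives an
independent normal draw of each category's stapler coefficient on the log
scale (SE from the CI as above); per-patient scenario costs are computed and
averaged, giving one total-difference draw per iteration (10,000 iterations
by default). Only the stapler coefficients (the decision-relevant terms) are
sampled; covariate coefficients cancel out of the between-scenario
difference in aggregate mode.

Draws are *moment-matched* by default (`mean_preserving=True`): the normal
draw is centered at `beta - se^2/2` so that the expected cost multiplier
`E[exp(draw)]` equals the base-case multiplier `exp(beta)`. This is the
standard parameterization when a log-scale parameter enters a decision model
multiplicatively; without it the lognormal mean shift (Jensen's inequality,
about +¥48 in total here) would bias every PSA draw away from the base case.
Setting `mean_preserving=False` exposes the uncorrected scheme (used in a
test to demonstrate the median converging to the base case as SEs shrink).
Cohort-level draws (`per_patient=False`) are available and produce an
interval roughly √388 times wider. A single seeded `numpy` generator drives
all draws, consumed category by category in a fixed order, so results are
bit-reproducible given the seed.

## The synthetic cohort generator

The generator emulates the study conditions of the reference cohort — two
stapler groups (powered n=296, manual n=92) — with:

* binary covariates drawn independently within group at the published
  prevalences (only marginals are published; real comorbidities correlate,
  so any joint-distribution property of real data is out of scope);
* age and BMI as truncated normals (published mean/SD; age clipped to
  [18, 100] years, BMI to [15, 45] kg/m², with BMI ≥ 40 — vanishingly rare
  under these parameters — falling into the top band);
* residence/insurance/histology/stage/site as per-group multinomials
  (renormalized; published percentages treated as complete-case
  proportions);
* stapler/cartridge counts as normals (1.2±0.6 / 1.2±0.5 and 7.0±3.9 /
  7.5±4.0), truncated below at zero and rounded to integers — so a zero
  count, and hence a zero acquisition cost, is possible;
* operational fields (operation time, length of stay, bleeding, drainage)
  drawn inside the eligibility envelope, so default cohorts pass the
  eligibility screen; filter behavior is tested on hand-built records;
* category costs as gamma draws with mean `exp(x'b)` from a coefficient
  table and fixed shape (`dispersion`). The default shape 4.94 makes
  SD/mean = 1/√4.94 ≈ 0.45, the ratio observed in the published drug-cost
  summary. `dispersion=None` gives noise-free costs `exp(x'b)` exactly —
  the oracle against which the regression module is verified to machine
  precision.

Comorbidities that appear in the reference equations but not in the
published baseline table carry one-time package-chosen prevalences
(cardiovascular 0.10, lung infection 0.10, tuberculosis 0.05, immune-system
/ breast / vascular 0.02); they are nuisance terms whose prevalence barely
affects the stapler contrast. The marital indicator is published as 100%
married in the manual arm, so it is constant in many replicates;
parameter-recovery fits exclude it (its omitted-confounding contribution to
the stapler coefficient is of order 1e-4).

What passing tests show: the pipeline recovers known generating parameters
(bias < 0.01 on the drug-cost stapler coefficient at the study's sample
sizes, 95% CI coverage 93-97% over 200 replicates) under the gamma noise
model. What they do not show: robustness to covariate correlation,
informative device selection, or cost distributions outside the gamma
family — properties of real hospital data the generator does not emulate.

## Eligibility screen

Exclusions (all strict inequalities; boundary values retained): operation
time > 8 h (stored in minutes, threshold 480), length of stay > 21 d,
bleeding > 600 ml, drainage > 2400 ml, death during surgery, non-routine
discharge. Every excluded episode reports *all* violated criteria. The
filter is idempotent, monotone in each threshold, and partitions its input
(property-tested).

## Statistical comparisons

Pooled Student's t for continuous variables (Welch behind a flag), Pearson
chi-square without continuity correction for categorical variables
(df=1 closed form; Fisher's exact automatically when any expected cell < 5,
where the chi-square approximation is invalid), Wilcoxon rank-sum for cost
variables (exact enumeration for untied samples of at most 25 per group,
tie-corrected normal approximation with mid-ranks otherwise). Two-sided
alpha 0.05 throughout; no multiplicity adjustment is applied.

## Problem sizes

Defaults: cohorts of 296/92, 10,000 PSA iterations over 388 model patients,
200 parameter-recovery replicates. These run in seconds on one core; the
full test suite takes well under a minute.

## Cohort CSV column dictionary

One row per surgical episode, UTF-8, comma-separated, header mandatory,
costs as plain CNY decimals:

| column | type | meaning |
|---|---|---|
| `patient_id` | str | opaque episode identifier |
| `group` | `powered`/`manual` | stapler group |
| `age` | years | age at surgery |
| `sex` | `male`/`female` | |
| `bmi`, `bmi_band` | kg/m², band label | band derived from `bmi` |
| `residence` | `provincial_capital`/`prefecture`/`county`/`other` | |
| `insurance` | `urban_employee`/`urban_resident`/`new_rural`/`other` | |
| `marital` | `married`/`single` | |
| `histology` | `squamous`/`adenocarcinoma`/`other` | |
| `stage` | `in_situ`/`I`-`IV` | tumor stage |
| `site` | lobectomy site label | e.g. `upper_left` |
| `comorb_*` | 0/1 | 19 comorbidity flags |
| `marrow_*` | 0/1 | 5 abnormal bone-marrow flags (INR, hemoglobin, erythrocyte, leukocyte, platelet) |
| `staplers_used`, `cartridges_used` | int ≥ 0 | devices expended |
| `operation_minutes`, `length_of_stay`, `bleeding_ml`, `drainage_ml` | numeric | eligibility fields |
| `died_in_surgery`, `discharge_routine` | bool | eligibility fields |
| `stapler_cost` … `other_cost`, `total_cost` | CNY | seven categories + total; `total_cost` must equal their sum (rtol 1e-6) |

## Known limitations

* The analysis is cost-minimization: clinical equivalence of the comparators
  is assumed, not modelled; no QALY/ICER layer.
* Aggregate-calibrated mode inherits any rounding or internal inconsistency
  of the published aggregate inputs.
* The univariable screening stage can only be validated against synthetic
  truth (the full candidate list behind the published table is not
  published).
* Single-admission costs in CNY; no discounting or currency conversion.
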