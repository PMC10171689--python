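# Methods

## Income instruments

**Self-report.** The total monthly income (INR) earned by all working
household members, as stated by the patient. Stored as a non-negative real;
missing when unanswered. Never transformed.

**International Wealth Index.** The IWI is a weighted sum over twelve
household items: ownership of television, refrigerator, phone, car,
bicycle, cheap utensils and expensive utensils; access to electricity; and
three-level (low/medium/high) quality codes for floor material, toilet
facility, number of rooms (0–1 / 2 / 3+) and water source. The packaged
weight table is the published IWI weight set; its minimum configuration
(no durables, everything "low") sums to exactly 0 and its maximum to
100.000002, so scores are clamped to [0, 100]. Clamping beyond this
rounding residue (1e-3) indicates a weight-table/rubric mismatch and
raises a warning. A recode rubric (also a replaceable data file) maps raw
survey vocabulary — floor-material, toilet-facility and water-source
strings in the conventional DHS-style groupings, plus room counts — onto
the score vocabulary; any unknown raw answer makes the whole asset block
missing rather than guessing a level.

The score converts to income by the published log-linear relationship

    income(s) = 1.489056 · exp(0.02918 · s)    [2015 USD/day]

The source prints the multiplicative constant and the exponent coefficient
without the exponent's argument; the only reading under which the formula
depends on the score is `exp(rate · s)`, which is what is implemented
(an explicit, recorded assumption). Daily 2015 USD becomes monthly
target-year INR by multiplying with `days_per_month` (default 30.44 =
365.25/12), `ppp_lcu_per_usd` and `cpi_ratio_target_over_base`.

**Choice of currency defaults.** The conversion factors are config inputs
because no single published value pins them down. The defaults are
`ppp_lcu_per_usd = 74.0` and `cpi_ratio_target_over_base = 1.306`
(2015→2021). The magnitude matters: the motivating cohort's published IWI
income distribution (median 37 491, IQR 25 421–61 322 INR/month) implies a
combined USD→INR multiplier near 97 — the 2021 market exchange rate times
a plausible CPI ratio. The consumption-PPP factor (~23 INR per
international $) would cap the achievable IWI monthly income near
25 000 INR, below that published median, so it cannot have been the factor
in use; it remains available by configuration. All results that depend on
these factors are treated as tolerance-checked, not exact.

**Picture-catalogue estimator.** A catalogue holds, per category (house,
kitchen, floor, toilet, bed), pictures tagged with the monthly income
(base USD) of the household photographed. The estimate is the arithmetic
mean of the five matched incomes × `ppp_lcu_per_usd`. Deliberately **no
CPI term** is applied — the estimator's published form converts with the
exchange factor only — an asymmetry with the IWI channel that is preserved
and surfaced in the run report. A partial selection (fewer than five
categories) is missing, not a partial mean: the formula divides by exactly
five. The packaged catalogue is synthetic (identifiers only): 30 pictures
per category with log-uniformly spaced incomes spanning 50–5000 USD/month,
matching the "about 30 per category" scale of the real tool.

## Agreement analysis

Per complete pair, difference = reported − estimated and pair mean =
(reported + estimated)/2, so an instrument that over-estimates income shows
negative differences. Because income differences are far from Gaussian,
the primary agreement summary is the proportion of pairs with
|difference| ≤ b for bands b = 25 000, 50 000, 100 000 INR (boundary
inclusive; the band list is configurable but must be strictly increasing).
Classical 95% limits of agreement are only permitted when a normality test
on the differences does not reject at α = 0.05: Shapiro–Wilk for
n ≤ 5000, D'Agostino K² above (where Shapiro's p-value becomes
approximate). Degenerate inputs (constant differences, n < 3) suppress
parametric limits by policy.

Distribution summaries use mean/SD plus median and quartiles by linear
interpolation between order statistics (numpy's default quantile rule,
stated here because several conventions exist). Kernel densities use a
Gaussian kernel with Scott's bandwidth on a grid clipped at zero income.

## Catastrophic expenditure

A patient is flagged catastrophic when total out-of-pocket payments (the
explicit total when recorded, else the sum of present direct-medical,
direct-non-medical and indirect components) satisfy

    OOP ≥ threshold · 12 · monthly_income

with threshold 0.25 by default (0.10 and 0.40 selectable; the 40%
convention normally applies to non-subsistence income, but no subsistence
deduction is possible without consumption data, so it is applied to total
income). Income is annualized because the published cohort medians (OOP
202 291 INR against monthly income 17 350 INR) are only consistent with a
rate near 80% — rather than ~100% — on an annual income basis; the basis
and the inclusive boundary are logged and configurable. Zero income is
degenerate: any positive OOP is catastrophic (warned). Cohort rates carry
Wilson 95% confidence intervals (statsmodels) and per-instrument
denominators; missing instruments shrink the denominator and are never
imputed.

## Synthetic cohort generator

The generator emulates the motivating 226-patient cohort from published
marginal summaries only; no joint income–expenditure statistic is
published, so the joint structure is an explicit modelling choice.

* **Marginals.** Each channel (self-report, IWI income, picture income,
  OOP expenditure) gets a log-normal fitted in closed form to its
  published (median, Q1, Q3): `mu = ln(median)`,
  `sigma = ln(Q3/Q1)/(2·z₀.₇₅)`. The fit reproduces the median and the
  quartile *ratio* exactly; the individual quartiles are reproduced
  exactly only for log-symmetric triples. The published self-report
  quartiles (10 000/17 350/40 000) are *not* log-symmetric — the upper
  quartile implied by the fit is `median·√(Q3/Q1)` = 34 700 INR, about 13%
  below the printed 40 000 — a structural limit of a two-parameter
  marginal anchored at the median, accepted rather than distorting the
  median. Heavier-tailed marginals (the real cohort's worst outliers were
  self-reported) are configurable but not calibrated.
* **Dependence.** One standard-normal latent wealth variable W per
  household; channel c draws `Z_c = ρ_c·W + √(1−ρ_c²)·ε_c` and maps Z_c
  through its marginal. Defaults: ρ = 1.0 for the three income channels
  (they measure the same construct) and ρ = 0.3 for expenditure — a weak
  positive wealth–spending link chosen as a conservative assumption and
  flagged as such.
* **IWI channel realization.** The target income inverts to a target score
  (`s = ln(income/base)/rate`, clamped to [0, 100] with the clamp fraction
  reported — with default currency factors about 12% of draws clamp at
  100, affecting only the upper tail). A deterministic bundle synthesizer
  then builds an asset bundle whose recomputed score approximates the
  target: greedy acquisition in descending-weight order (categoricals
  upgrade stepwise) without overshooting, then a deterministic hill climb
  over single toggles/level shifts and removal+addition swaps until within
  1.25 points of the target or no move improves. Across a 0.01-spaced grid
  of targets the worst realized error is 1.25 score points; bundles are
  cached per target rounded to 0.01 points, so large cohorts cost one
  synthesis per distinct rounded target.
* **Picture channel realization.** The target income converts to base USD,
  is perturbed per category by log-normal noise (σ = 0.25, a realistic
  picture-matching scatter chosen once), and snaps to the catalogue
  picture with the nearest log income (ties toward the lower income).
* **Expenditure and demographics.** OOP totals come straight from the
  expenditure marginal. Demographic variables (age band, sex, education,
  job skill, household size, travel distance, hospital type, cancer site,
  stage, treatment intent) are sampled independently from the cohort's
  published frequency table; they add realism to the tables but carry no
  wealth dependence.
* **Missingness.** By default exactly one household misses the asset
  questionnaire and another the picture selection, mirroring the cohort's
  99.5% completion.
* **Seeding.** One integer seed feeds a `SeedSequence` split into eight
  documented streams (shared latent, the four channel noises, picture
  noise, demographics, missingness), so runs are bit-reproducible and
  adding draws to one stream does not disturb the others.

**What passing tests do and do not show.** The generator matches the
published marginal medians and the discretization behaviour of the two
estimators; it does not reproduce the real cohort's joint reporting-bias
structure (the funnel-shaped Bland–Altman pattern, self-reported outliers,
income-dependent agreement). Pipeline results on synthetic cohorts
therefore validate the *machinery* and the qualitative orderings (e.g.
CE rate self-reported > IWI > picture tool), not the cohort's published
agreement percentages.

## Numerical and policy choices

* Quantile rule everywhere: linear interpolation between order statistics.
* Band membership and the CE boundary are inclusive (≤, ≥).
* Money is kept as non-negative float INR; rounding only at presentation.
* CSV exchange: comma-separated UTF-8 with header; empty cell = missing;
  malformed rows are rejected with their line number, duplicate patient
  ids abort the load.
* Analysis problem sizes: calibration checks use 100 000 households (the
  scale at which median sampling noise, ~0.5%, is well inside the 2%
  continuous-channel tolerance); pipeline and ordering checks use the
  study-sized default of 226.

## Configuration schema

```yaml
economic:
  ppp_lcu_per_usd: 74.0          # USD -> INR multiplier (> 0)
  cpi_ratio_target_over_base: 1.306  # CPI(target)/CPI(base) (> 0)
  days_per_month: 30.44
  base_year: 2015
  target_year: 2021
ce:
  threshold_fraction: 0.25       # in (0, 1); 0.10 / 0.40 selectable
  income_basis: annualized_monthly
  boundary_rule: geq
generator:
  n: 226
  seed: 42
  selection_noise_sigma: 0.25
  n_missing_iwi: 1
  n_missing_gapminder: 1
  # marginals / latent_correlations / demographics_frequencies accept the
  # structures documented in wealthproxy.synthetic_cohort
```

Unknown keys warn and are ignored; every constant's provenance
(user/default) is recorded in the run report.

## Known limitations

* The IWI truncates: households beyond the asset ceiling are
  indistinguishable, compressing the upper income tail (visible as target-
  score clamping in the generator).
* The picture-catalogue income base (income vs consumption vs imputed
  wage) is opaque; incomes are treated as opaque matched values.
* One LCU/USD pair per run; no impoverishment metrics, no longitudinal
  cost trajectories, no subsistence-adjusted (40% non-subsistence) CE.
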