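# Methods

This note records the models, definitions, numerical conventions and
design decisions behind `cgmdiet`, in the spirit of a statistical
software methods appendix. It states no empirical result that the test
suite does not itself compute.

## Glycemic load

A meal's glycemic load is `MealGL = Σᵢ GIᵢ · gCarbsᵢ / 100` over its food
items, GI on the conventional 0–150 scale and carbohydrate mass in
grams. GL is therefore homogeneous of degree 1 in carbohydrate mass and
additive over meal parts; both properties are enforced by property
tests. If any item lacks a validated GI, the whole meal is excluded from
GL analysis (returned as missing) but still contributes to daily
macronutrient totals. GI lookup is an exact, case-insensitive string
match against the table — deliberately no fuzzy matching, since partial
matching would inject an untestable bias into table coverage.

Days are half-open intervals `[00:00, 24:00)` local time; a meal logged
at 23:59 and one at 00:01 belong to different days.

### Outlier filters

Gross diary-entry errors (e.g. a portion logged in the wrong unit) are
removed by z-score filters computed over the pooled analysis series
(all matched meal GLs; all daily energies), not per participant —
defaults z > 3 for GL and z > 6 for energy. Two consequences worth
knowing:

* With the pooled sample SD, the largest attainable |z| in a sample of n
  values is `(n−1)/√n`; a z > 3 exclusion is impossible below n = 11 and
  z > 6 below n = 38. The filter is honest about this: it simply returns
  all indices.
* A single gross outlier inflates the pooled SD, which *masks* moderate
  natural outliers; in the injection scenario used for validation the
  filter removes exactly the tampered record.

Whether the energy filter operates on per-meal energies or daily totals
is a configuration switch (`energy_z_basis`); the pipeline default is
daily totals.

## Windowed CGM metrics

Postprandial windows are closed intervals `[anchor, anchor + d]`,
d ∈ {2,…,6} h, anchored at the scan-derived intake time; daily windows
are `[00:00, 24:00)`. A window is **insufficient** when fewer than
`min_coverage` (default 0.8) of the samples expected at the sensor's
nominal cadence (15 min) are present; insufficiency is a value that
propagates to exclusion counts, never an error, and no interpolation or
imputation is ever performed.

Landmarks: the **peak** is the highest interior local maximum (a sample
strictly greater than both neighbours, value ties broken earliest); when
a window is monotone and has no interior maximum, the global maximum is
used as fallback. The **trough** is the first interior local minimum
after the global maximum, falling back to the window-end sample (making
the fall-time 0 for windows that end while glucose is still rising).

The 19 metrics: total trapezoidal `auc` (not baseline-corrected — the
incremental AUC is a distinct metric and deliberately out of scope),
`auc_rise` (intake→peak) and `auc_fall` (global max→trough); relative
amplitude `amp` (peak minus glucose at intake) and window minimum
`amp_min`; `t_rise`, `t_fall`; chord slopes `slope_rise = amp/t_rise`,
`slope_fall = (trough − max)/t_fall`, their ratio
`slope_ratio = slope_rise/|slope_fall|`; finite-difference `slope_avg`
and `slope_steepest`; sample `mean`, `sd` (n−1 denominator),
`var = sd²` (computed literally as the square so the identity is
bit-exact), `cv = 100·sd/mean`, bias-corrected `skew` and excess
`kurtosis`; and `mage`. Degenerate conventions: a flat segment of zero
duration has slope 0 (so a constant window reports all slopes 0), while
a nonzero change over zero time is undefined (NaN); zero-variance
windows yield NaN skew/kurtosis.

### MAGE

MAGE is the mean amplitude of glycemic excursions: collapse plateaus,
take the alternating turning points of the series, call an excursion
qualifying when its amplitude exceeds one SD of the *same window*, and
average the qualifying amplitudes measured in the direction (rise or
fall) of the first qualifying excursion; 0 when none qualifies. Using
the window-local SD is what makes MAGE meaningful on 2–6 h windows as
well as days. The implementation is validated against an independently
written turning-point oracle on hundreds of random traces.

## Synchronization

Scan annotations are treated as the ground-truth intake times. Matching
is greedy by smallest absolute gap within a tolerance (default 30 min —
not empirically derived, hence a named configuration knob), restricted
to same participant and agreeing meal type; each annotation serves at
most one meal. Only main meals (breakfast/lunch/dinner) enter windowed
analysis; snacks and drinks contribute to daily aggregation only. A
later meal inside an earlier meal's window is kept but flagged
(`overlap`) so sensitivity analyses can drop such windows.

## Correlation study

The family is fixed at 119 tests: GL against each of the 19 windowed
metrics over five windows (95), plus energy/carbohydrate/fiber/sugar
against the six daily metrics (24). Method choice is gated by
Shapiro–Wilk at 0.05: Pearson only when both members pass, Spearman
otherwise. The gate's unit is configurable — per pair on the
pairwise-complete cases (default; the conservative reading) or once per
variable — because study descriptions of "data not normally distributed"
are usually ambiguous between the two. Missing metric values are dropped
pairwise. Family-wise control is Bonferroni: α = 0.05/119 ≈ 4.2×10⁻⁴
(0.0004 at one significant figure). Q-Q plots are written on request
alongside the test rather than silently.

## Mixed models

All seven models are random-intercept LMMs fitted by REML with
`statsmodels` MixedLM: three GL models (2/3/4 h windows) on AUC, Amp and
Var, and four daily macronutrient models on SD and MAGE, optionally plus
personal characteristics (sex code, moderate and sedentary activity,
age, waist circumference, muscle mass, body fat, sleep). SD and Var are
never allowed in one design — Var is a strictly monotone transform of SD
(Spearman ρ = 1), and the constructor enforces the guard. Singular
designs fail loudly, naming the collinear columns.

Validity mirrors conventional residual diagnostics: Shapiro–Wilk on the
residuals and a Levene test of residual spread across fitted-value
tertile bins, both requiring p ≥ 0.05. (Study reports sometimes phrase
the homoscedasticity criterion with the opposite inequality; under
Levene, p < 0.05 *rejects* homoscedasticity, so the conventional
direction is used here.)

Validity verdicts are sample-size sensitive: Shapiro–Wilk's power grows
with n, so on large simulated cohorts (hundreds of meals) even small
departures from residual normality are flagged and models read
"invalid", while the same generating process at a small study's size
passes. This mirrors how such diagnostics behave on real cohorts and is
a property of the tests, not a defect of the models.

Cross-validation leaves out one *participant* at a time — the question
is performance on a new person, not a new meal — and predicts the
held-out subject from fixed effects alone, since a new participant's
random intercept is unidentified. MAE is computed per participant and
summarized by mean and SD across folds; failed folds are skipped with a
warning and reduce the fold count.

The published-equation evaluators (`predict_published_gl2h`,
`predict_published_energy`) are exact linear forms over documented
coefficients; sex coding defaults to female = 0 / male = 1 and is
configurable because published equations rarely document the coding, and
activity/sleep covariates enter in hours per day (the equation's small
sleep coefficient suggests its original unit may differ; the choice is
explicit and overridable by rescaling inputs).

## Synthetic cohort

The generator emulates a one-week free-living study in healthy adults
aged 25–34. Demographics are truncated normals per sex matching the
emulated cohort's published means/SDs (e.g. female waist 77.4 ± 11.7 cm,
male 86.5 ± 6.7 cm), with an exact 27:21 female:male split at n = 48.
Diaries log three main meals (clock-time jitter around 7:45/12:30/18:30)
plus 0–3 snacks per day (P = .45/.35/.15/.05, mean ≈ 0.85/day — chosen
so cohort totals at 48 participants × 7 days are of the same order as a
real study's ~600 mains and ~290 snacks); item carbohydrate masses are
log-normal. A configurable fraction of items is off-table (no GI entry;
default 0.3), emulating strict GI-table coverage; meal timing
distributions are defaults, not inferred from data.

CGM traces follow

```
glucose(t) = baseline + A·sin(2π(h−7)/24) + Σ_meals gain·GL·k(t−t_meal) + ε
```

with `k` a log-normal-shaped kernel: unit peak at `time_to_peak`
(default 45 min), width set so the kernel halves a `decay_time`
(60 min) after the peak. The kernel is smooth and single-peaked, so
rise/fall landmarks are unambiguous on clean traces, and meal
contributions superpose additively (a tested invariant). Defaults:
baseline 5.2 mmol/L with 0.35 mmol/L between-participant spread
(healthy non-diabetic means sit below 6.2 mmol/L), circadian amplitude
0.3 mmol/L, gain 0.05 mmol/L per GL unit (a GL-25 main meal produces a
~1.25 mmol/L excursion), Gaussian reading noise 0.3 mmol/L truncated so
glucose stays above 1 mmol/L, 15-min sampling. Scan gaps can be
emulated by removing random contiguous blocks (`thin_trace`), and a
unit-entry error by multiplying one meal's portions by a large factor
(`inject_portion_outlier`) — the diary is corrupted, the ground-truth
channel is not.

What the generator does **not** emulate: insulin–glucose physiology
(the response is a fixed kernel, not a dynamical model), sensor drift or
calibration error, correlated noise, under-reporting of intake, or
meal-composition effects beyond GL (fat/protein modulation of the
response). Passing recovery tests therefore show that the pipeline's
statistics faithfully extract structure *of the assumed form*; they do
not certify performance on real cohorts, where effect sizes are smaller
(real GL–amplitude correlations are moderate, ρ ≈ 0.4, versus ≈ 0.7 on
clean synthetic data).

## Validation problem sizes

The test suite validates parameter recovery on 100 cohorts drawn
directly from the known random-intercept generating process at a
study-like size (26 participants × ~4 meals), requiring mean
fixed-effect bias under 10%; correlation recovery on three full
forward-model cohorts (48 participants × 7 days); and family-wise error
control on 18 independent null cohorts (meal-response gain 0), requiring
the observed FWER over the 119-test family to stay within two
Monte-Carlo standard errors of 0.05. These sizes were chosen as the
smallest giving clearly interpretable pass/fail margins for each claim.

## Known limitations

* Windowed metrics are computed on observed samples only; on sparse
  irregular traces the chord-slope and AUC estimates inherit the grid.
* The MAGE direction rule (first qualifying excursion) follows the
  classic algorithm; other published MAGE variants (e.g. averaging both
  directions) will differ on asymmetric traces.
* The matching step assumes annotations are honest intake markers;
  systematically late scanning would bias all windowed metrics together.
* Exclusion accounting is exact but coarse: a meal excluded for several
  reasons is counted at the first stage that drops it.
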