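# cgmdiet

Diet monitoring from continuous glucose monitoring (CGM) in people
without diabetes. `cgmdiet` implements a complete, tested analysis
pipeline connecting free-living food diaries to wearable glucose sensors:

* **Glycemic load (GL)** per meal from glycemic-index (GI) tables:
  `MealGL = Σᵢ GIᵢ · gCarbsᵢ / 100`, with strict exclusion of meals
  containing any food of unknown GI.
* **19 windowed postprandial CGM metrics** on 2–6 h windows anchored at
  food intake (total trapezoidal AUC and its rise/fall parts, relative
  amplitude, rise/fall times, chord and finite-difference slopes, sample
  moments, MAGE), plus **6 daily metrics** (AUC, mean, SD, MAGE, CV, Var)
  on midnight-to-midnight windows.
* **Diary↔CGM synchronization** via the sensor-scan annotations
  participants make before meals (greedy nearest-in-time matching within
  a tolerance).
* A **normality-gated correlation study** — 119 tests (GL × 19 metrics ×
  5 windows + 4 macronutrients × 6 daily metrics), Pearson where both
  variables pass Shapiro–Wilk, Spearman otherwise, Bonferroni-controlled
  at α = 0.05/119 ≈ 0.0004.
* **Linear mixed models** with participant random intercepts
  (`y_ij = β₀ + x'_ij β + b_i + e_ij`, REML) predicting GL from
  AUC/Amp/Var and daily macronutrient intake from SD/MAGE plus personal
  characteristics, with residual-validity diagnostics and
  leave-one-participant-out MAE.
* A **synthetic cohort generator** (demographics, diaries with missing-GI
  and unit-error noise, CGM traces from a meal-response forward model)
  so the whole pipeline can be exercised and validated without access to
  a real cohort.

Who it is for: researchers analysing CGM + food-diary studies in healthy
populations, and anyone needing reference implementations of windowed
postprandial glucose metrics (including a window-local MAGE) with
explicit, tested exclusion rules.

## Worked example

```python
from datetime import datetime
from cgmdiet import FoodItem, MealRecord, meal_gl, predict_published_gl2h

meal = MealRecord(
    "P001", datetime(2024, 3, 4, 12, 30), "lunch",
    items=[FoodItem("white rice", grams_carbs=45.0, energy=320.0,
                    fiber=1.2, sugar=0.3, gi=73.0),
           FoodItem("lentils", grams_carbs=20.0, energy=150.0,
                    fiber=4.0, sugar=1.0, gi=32.0)],
)
print(f"meal GL = {meal_gl(meal):.1f}")
print(f"predicted GL (2 h, AUC=660, Amp=1.8, Var=0.25) = "
      f"{predict_published_gl2h(auc=660.0, amp=1.8, var=0.25):.1f}")
```

prints

```
meal GL = 39.2
predicted GL (2 h, AUC=660, Amp=1.8, Var=0.25) = -24.6
```

The GL is 73·45/100 + 32·20/100 = 32.9 + 6.4 ≈ 39.2 GL units. The second
line evaluates the published two-hour fixed-effect equation
GL = −23.0 + 0.001·AUC − 3.56·Amp + 16.7·Var at a typical flat
postprandial response; strongly negative predictions like this simply
reflect a window with little glucose excursion.

An end-to-end run on a simulated 12-participant, 7-day cohort:

```bash
cgmdiet run-all --seed 7 --out run/
```

```python
from cgmdiet.pipeline import RunConfig, run_pipeline
from cgmdiet.synthetic import CohortScenario

cfg = RunConfig(scenario=CohortScenario(n_participants=12, days=7, seed=7),
                outdir="run")
manifest = run_pipeline(cfg)
```

The manifest reports, among others: 252 main meals recorded, 116 with a
computable GL, 214 matched to sensor scans, 1 GL outlier excluded by the
z > 3 filter, 119 correlations at family alpha 0.00042, and 7 fitted
mixed models. In the written `correlations.csv`, GL vs relative
amplitude on the 4 h window comes out as Spearman ρ = 0.75
(p = 7.4×10⁻¹⁹, significant) — the simulated meal-response gain makes
the diet→glucose coupling recoverable end to end.

The CLI exposes each stage separately (`simulate`, `gl`, `metrics`,
`sync`, `correlate`, `model`); stages exchange plain CSVs so any stage
can run standalone on your own data in the same column layout.

## Layout

```
src/cgmdiet/
  synthetic.py     # cohort, diary, annotation and CGM-trace generators
  diary.py         # GL computation, daily intake, z-score filters
  metrics.py       # 19 windowed + 6 daily CGM metrics, MAGE, windows
  sync.py          # meal-to-annotation matching, analysis-table assembly
  correlations.py  # normality gate, 119-test family, Bonferroni
  lmm.py           # mixed models, LOOCV, published-equation evaluators
  pipeline.py      # orchestration + exclusion-accounting manifest
  cli.py           # click CLI
docs/methods.md    # modelling and design notes
```
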