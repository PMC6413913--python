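# aeropower

Predicting **Wingate anaerobic test** outputs — peak power (PP), mean power
(MP), both in watts, and the fatigue index (%) — from a **maximal incremental
cardiopulmonary exercise test (CPET)**.

The Wingate test is a 30-s all-out cycle sprint against a braking load of
0.075 × body mass; it is the standard measure of anaerobic mechanical power
but is extremely strenuous. A maximal incremental treadmill CPET, in
contrast, is routine in exercise physiology labs. `aeropower` implements the
full analysis chain for predicting the anaerobic outputs from the aerobic
test alone, for exercise physiologists, sport scientists and
methods-oriented biostatisticians:

1. **Feature extraction** — 51 canonical aerobic features per subject
   (12 directly measured channel maxima, 39 calculated), including the
   ventilatory anaerobic threshold (VAT) found by the **V-slope method**
   (exhaustive two-segment least-squares breakpoint of VCO₂ vs VO₂).
2. **Greedy stability-selection regression** — the predictor is a linear
   equation on standardized features,

   `outcome = α + β·feature₁ + γ·feature₂ + δ·feature₃ + …`

   built by forward selection (each step adds the feature minimizing the
   train SSE of the OLS fit), terminated when the added predictor's adjusted
   R² falls more than 2% (relative) below the current one, voted over 1000
   random 40:30 train/test re-splits of the calibration pool (stratified on
   VO₂max tertiles), refit on the consensus features, and scored on a
   held-out validation subset across 100 outer repeats (Spearman r, RMSE,
   mean ± SD % error).
3. **Correlation-network clustering** — the 51×51 Spearman matrix of the
   features, thresholded to the top 30% of pairwise correlations, is
   clustered by Newman **leading-eigenvector modularity** maximization
   (recursive spectral bisection with vertex-moving fine-tuning),

   `Q = (1/4m) Σᵢⱼ (Aᵢⱼ − kᵢkⱼ/2m)(SᵢSⱼ + 1)`.
4. **Synthetic cohort simulator** — breath-by-breath treadmill CPETs
   (speed +1 km/h per minute; grade rising 2%/min once the respiratory
   exchange ratio reaches 1.0; termination at maximal heart rate) paired
   with Wingate outcomes *planted* as a known linear function of the
   standardized features plus noise, so selection, clustering and metrics
   are all testable against ground truth.

The regression and clustering are exposed as scikit-learn estimators
(`GreedyStabilityRegressor`, `ModularityClustering`, `FeatureStandardizer`)
and compose with sklearn pipelines and model selection; module-level
functions (`greedy_select`, `stability_select`, `cluster`, …) are thin
wrappers over the same machinery.

## Worked example

```python
from aeropower import GreedyStabilityRegressor, evaluate, simulate_cohort

cohort = simulate_cohort(88, seed=7)          # 36 women / 52 men, planted truth
X, y = cohort.features, cohort.outcomes["pp_w"]

model = GreedyStabilityRegressor(n_runs=200, random_state=0).fit(X.iloc[:60], y.iloc[:60])
m = evaluate(y.iloc[60:], model.predict(X.iloc[60:]))
print(f"held-out Spearman r = {m.spearman_r:.2f}, RMSE = {m.rmse:.0f} W, "
      f"% error = {m.pct_err_mean:.1f} +/- {m.pct_err_sd:.1f}")
```

prints

```
held-out Spearman r = 0.74, RMSE = 58 W, % error = 6.9 +/- 7.3
```

i.e. on 28 held-out subjects the consensus equation ranks peak power with
r = 0.74 and predicts it to within about 7% on average — the cohort's
outcome was planted at population R² = 0.9 on six aerobic features, and
`cohort.truth["pp_w"]` exposes those features and coefficients for
comparison with `model.frequencies_`.

The same flow from a shell:

```bash
aeropower simulate --n 88 --seed 7 --out cohort/
aeropower extract  --in cohort/ --out features.csv
aeropower train    --features features.csv --manifest cohort/manifest.csv \
                   --outcome pp_w --n-runs 200 --n-outer 20 --seed 0 --out model.json
aeropower predict  --model model.json --features features.csv
aeropower cluster  --features features.csv --top-fraction 0.30 --out partition.json
aeropower run      --seed 7 --out results/        # full pipeline + report
```

Two reference prediction equations (the published six-feature PP and
four-feature MP equations, coefficients on standardized features) ship as
JSON fixtures; `aeropower.reference_equations()` loads them, and evaluating
either at the all-zero standardized vector returns its intercept (638.4 W
for PP, 476.8 W for MP).

## Layout

```
src/aeropower/
  registry.py    the 51-feature registry (names, classes, stages, aliases)
  vat.py         V-slope two-segment breakpoint search
  features.py    feature extraction + FeatureStandardizer
  profiles.py    subject/protocol/Wingate/generative domain types
  simulate.py    CPET + Wingate + cohort simulators, planted designs
  selection.py   greedy selection, stability voting, protocol, estimator
  network.py     correlation network + Newman modularity clustering
  io.py          CSV/JSON readers-writers, RunConfig
  pipeline.py    end-to-end run with deterministic report bundle
  cli.py         `aeropower` command group
docs/methods.md  model, assumptions, parameter choices, limitations
```
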