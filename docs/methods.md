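# Methods

This note documents the models, algorithms and design choices behind
`aeropower`: what each stage computes, the assumptions it makes, the
parameters that matter, and what the synthetic data do and do not emulate.

## 1. The prediction problem

A maximal incremental CPET yields breath-by-breath gas exchange (VO₂, VCO₂,
VE), respiratory frequency, tidal volume, heart rate and the treadmill
schedule. The Wingate anaerobic test yields peak power PP [W] (maximum over
the 30-s sprint), mean power MP [W] (30-s time average) and the fatigue
index [%] (percent drop from maximal to minimal power). The package's
premise is that the aerobic test carries enough information about the
anaerobic energy systems that a linear equation on standardized aerobic
features predicts PP and MP usefully; fatigue is supported as an outcome but
excluded from default reports because it is essentially unpredictable from
aerobic features (the simulator plants it at population R² = 0.16,
i.e. r = 0.4). Anthropometric variables (mass, height, BMI) are never
candidate predictors.

## 2. Feature registry (51 features)

The registry (`aeropower.registry`) fixes 12 *direct* features — smoothed
maxima / terminal values of the measured channels (test duration, VE, VO₂,
VCO₂, VT, RF, RR, HR, treadmill speed and grade, RER, VO₂ per kg) — and 39
*calculated* features: ventilatory equivalents, channel-on-channel
regression slopes, minute-wise VO₂ levels and slopes for minutes 1–4 of the
incremental phase (the *early-minutes* stage), the VAT-anchored block, and
intensity composites (grade × speed products and ratios).

Decisions a reader should know about:

* **Smoothing.** Channel maxima are taken on a 10-breath rolling mean
  (configurable; recorded in provenance) because breath-by-breath maxima are
  noise-dominated.
* **"max RF" vs "max RR".** Both exist: RF is the metabolic cart's
  respiratory-frequency channel; RR is the respiratory rate derived from the
  breath timestamps (60 / inter-breath interval). On ideal data they agree;
  on real exports they need not.
* **Provisional formulas.** A few historical feature names have no unique
  published definition. The registry ships explicit provisional readings —
  "VO2-1 at VAT" = VO₂ at the breakpoint [ml/min]; "VO2-2 at VAT" = VO₂ at
  VAT relative to max VO₂ (relative rather than per-kg to avoid an exact
  duplicate of "VO2 [ml/min/kg] at VAT"); likewise VCO2-1/VCO2-2; "VSLOPE" =
  the single-segment slope of VCO₂ on VO₂; "predicted VO2" = the below-VAT
  VO₂-vs-time line extrapolated to test end; "predicted VO2 at VAT / the
  real VO2 at VAT" = that line evaluated at the VAT time over the measured
  value. Every one of these is overridable per name via
  `extract_features(..., overrides=...)`, so an alternative reading is a
  configuration, not a fork.
* **Minute windows** are half-open, `[60(k−1), 60k)` seconds from the end of
  the warm-up, with slopes computed against time in minutes.
* **Missing features.** A subject whose V-slope fit is unreliable (below)
  gets all VAT-anchored features flagged missing and is dropped from the
  cohort feature matrix with a logged reason. Dropping is conservative and
  visible; imputation is deliberately not offered.

## 3. VAT detection (V-slope)

Breaths of the incremental phase are sorted by VO₂ and VCO₂ is regressed on
VO₂ with an exhaustive two-segment least-squares search: every split with at
least 5 points per segment is scored by total SSE (prefix-sum
implementation, O(n) after sorting) and the minimizing split is the
breakpoint. The fit is *reliable* only if the two-segment SSE improves on
the single-line SSE by at least 5% (configurable) **and** the upper slope is
at least as steep as the lower one — a "breakpoint" where CO₂ output turns
shallower is not a ventilatory threshold. Perfectly linear input therefore
reports `reliable = False` rather than a spurious break.

Accuracy: with the breakpoint planted at VO₂ = 2000 ml/min and Gaussian
noise at 1% of the VCO₂ range on a breath-realistic grid (~300 points,
matching a ~10-minute ramp at ~2-s breaths), the median recovery error over
100 seeded replicates is below 5%; on noiseless input the breakpoint is
exact to one grid point. Sparser grids degrade gracefully (the error scales
roughly with grid spacing).

## 4. Standardization

Features are standardized column-wise to mean 0, SD 1, with the **n − 1**
(sample) denominator — conventional for small cohorts. Zero-variance columns
raise a named error rather than silently producing NaN. By default the
scaler is fitted on the calibration pool only and applied to the validation
subset (leak-free); the `global_standardize` flag instead standardizes globally
before splitting, reproducing the common but leaky variant. Fitted
parameters travel inside every serialized equation, so a saved model can be
applied to raw feature rows.

## 5. Greedy stability-selection regression

One selection run, given standardized train and test subsets:

1. start from the intercept-only model;
2. for every remaining candidate, fit OLS of the outcome on the current
   features plus that candidate and record the train SSE (implemented with
   Gram-matrix/Schur-complement updates — a full protocol executes on the
   order of 10⁵ fits, and the incremental form is ~100× faster than
   refitting; final coefficients are always re-solved by `lstsq`, and tests
   cross-check them against scikit-learn's `LinearRegression`);
3. add the candidate with the smallest SSE (ties: lowest registry index;
   collinear candidates with a vanishing Schur complement are skipped and
   logged);
4. record the test-subset Spearman correlation of the updated model
   (monitoring only — it does not influence selection);
5. stop when the added predictor's adjusted R²,
   `1 − (1 − R²)(n − 1)/(n − p − 1)`, is more than 2% below the current
   model's and return the pre-drop model. "2% smaller" is read as
   *relative* (`adj_new < 0.98 · adj_cur`); the absolute reading (−0.02) is
   available via `absolute_drop=True`. Additional stops: perfect fit
   (train R² = 1 within 1e−12, the planted-noiseless case), an exhausted
   candidate pool, and the sample-size limit `n ≤ p + 2`.

**Stability voting.** Because a single random split produces an unstable
feature set, the run is repeated `n_runs = 1000` times over fresh 40:30
train/test re-splits of the calibration pool (stratified on VO₂max
tertiles; independent seeded streams spawned from one master seed). A
feature's frequency is the fraction of runs selecting it; the *consensus*
set keeps features at frequency ≥ 0.5 (threshold configurable — the rule is
a package choice for "most common"), ordered by frequency with ties broken
by earlier mean selection position. The consensus equation is an OLS refit
on the whole calibration pool; if nothing clears the threshold the single
most frequent feature is kept so a predictor always exists.

**Outer protocol.** `run_full_protocol` repeats
{stratified 40/30/30 split → standardize on calibration → stability vote →
consensus refit → evaluate on validation} `n_outer = 100` times and reports
the per-repeat and aggregate mean/SD of the validation Spearman r, RMSE and
percent error (percent error uses the observed value in the denominator;
non-positive observations are excluded with a log entry; Spearman uses
average ranks and is flagged undefined for constant predictions).

An honest behavioural note: at population R² ≈ 0.9 with a calibration pool
of ~60 subjects (train ≈ 35), the relative 2% stop rule rarely fires before
the sample-size limit, so individual runs select many features and consensus
sets are large (tens of features). The voting frequencies still rank the
planted signal features at the top, and the protocol's aggregate metrics are
stable across scaled-down and scaled-up replications (the acceptance suite
asserts agreement within ±0.05 mean Spearman between a 50×20 and a 200×80
configuration), but users interested in sparse equations should lower
`max_features` or raise the consensus threshold.

**Stage filters.** `stage="early_minutes"` restricts candidates to the 8
minute-wise features (minutes 1–4), reproducing the early-prediction
variant; on cohorts whose signal is planted on full-test features the
early-minutes model scores strictly lower (e.g. mean validation Spearman
0.64 vs 0.84 at the 50×20 scale on the default 88-subject cohort).

## 6. Correlation-network clustering

The 51×51 Spearman matrix of the features (across subjects) is thresholded
to a network: the C(51,2) = 1275 off-diagonal pairs are ranked by |ρ| and
the top ⌈0.30 · 1275⌉ = 383 become edges with weight |ρ| (absolute value,
since modularity assumes non-negative weights; a binary mode sets weights to
1; ties at the cutoff break by lexical feature-name order). "Top 30%" is
read as an *edge* percentile — thresholding correlations is the standard
construction — with the node-subset reading out of scope. All 51 nodes are
retained, isolated or not.

Modularity of a two-group membership S ∈ {±1}ⁿ is
`Q = (1/4m) Σᵢⱼ (Aᵢⱼ − kᵢkⱼ/2m)(SᵢSⱼ + 1)` with k the node strengths and m
the total edge weight. Clustering proceeds by recursive bisection: the
leading eigenvector of the generalized subgroup modularity matrix
(restricted B with restricted row sums subtracted on the diagonal, so each
split's ΔQ is exactly its contribution to the global Q) gives the initial
split (zero entries join the +1 side), which is then refined by the
**vertex-moving fine-tuning sweep** — repeatedly move the single vertex
whose side change most increases ΔQ, each vertex once per sweep, keep the
best intermediate state, iterate while sweeps improve. The fine-tuning stage
is kept because, measured on seeded random graphs of ≤ 10 nodes, the raw
eigenvector sign split misses the exhaustive-best bisection on roughly a
quarter of replicates, while with refinement all replicates match the
exhaustive oracle; `fine_tune=False` exposes the raw split. A group is
indivisible when the leading eigenvalue or the refined ΔQ is ≤ 1e−10; the
recursion returns the labels, the division tree with per-split ΔQ, and Q
recomputed from the labels (equal to the accumulated Σ ΔQ within 1e−9).

On study-like feature matrices the partition is read against the familiar
three blocks: channel maxima / intensity composites, VAT-anchored V-slope
anatomy, and ventilatory-equivalent / relative-timing features. The number
of groups found on simulated cohorts (typically 3–5) depends on the noise
model and is not forced to 3.

## 7. Synthetic cohort generator

The simulator's purpose is statistical, not physiological: it produces data
with exactly the structure the analysis assumes, with known truth.

* **Anthropometrics** per sex from truncated normals (±3 SD, physiologic
  floors) matching the reference cohort summary (36 women / 52 men; women:
  VO₂max 2585.9 ± 382.7 ml/min, VE max 87.2 ± 14.5 l/min, HR max 183 ± 7.8;
  men: 4169.2 ± 605.8, 146.5 ± 20.6, 186 ± 7.3; ages 25 ± 4 / 28 ± 6;
  mass 60.7 ± 8.7 / 75.8 ± 10.2 kg; height 164.3 ± 6.4 / 176.6 ± 6.8 cm).
  The VAT fraction is drawn from a truncated normal 0.63 ± 0.05 on
  [0.50, 0.72] — a realistic threshold range whose upper bound also
  guarantees the RER trigger fires before termination, so the treadmill
  grade features are defined for every subject.
* **Protocol.** 2-min warm-up at low speed (the study protocol's warm-up and
  starting speeds are not published; defaults 4 and 7 km/h are configurable
  package choices, not inferred values), speed +1 km/h per minute. Once the
  *measured* (noisy) RER reaches 1.0 — latched, as a metabolic cart would —
  the grade rises 2% immediately and a further 2% each subsequent minute.
  The per-minute grade reading of the protocol is deliberate: a single
  one-time increment would make "max slope" constant across any cohort,
  which degenerates standardization and the correlation network, and
  continued grade increments match standard incremental treadmill practice.
* **Physiology.** VO₂ ramps linearly from 30% of VO₂max to VO₂max over a
  subject-specific ramp (duration = VO₂max·kg⁻¹ / 5.5 min·ml⁻¹, clipped to
  6–14 min, so fitter subjects run longer); VCO₂ follows a two-segment
  V-slope (slopes 0.90 below / 1.30 above the planted VAT, hence RER is 0.90
  below threshold and crosses 1.0 exactly once, at 4/3 of the VAT fraction);
  VE is piecewise linear in VO₂ reaching 60% of VE max at the VAT; HR is
  linear in %VO₂max from a resting 70 bpm, and the test ends at the breath
  where modeled HR reaches HR max. Breaths arrive every 2 ± 0.5 s (uniform
  jitter); channels carry multiplicative Gaussian noise (2% VO₂/VCO₂, 3%
  VE). One master seed spawns independent per-subject streams
  (`numpy.random.SeedSequence`), so cohorts are bit-reproducible and
  parallel-safe.
* **Outcomes.** PP, MP and fatigue are planted as
  `intercept + Σ coef · z(feature) + N(0, σ)` on the cohort-standardized
  features. Defaults use the six-feature PP and four-feature MP reference
  structures at population R² = 0.9 (the predictive strength the method is
  designed to achieve) and a weak fatigue signal at R² = 0.16; `target_r2`
  resolves σ from the realized signal variance, or σ can be given directly.
  Wingate power curves consistent with the planted values (peak = PP, end =
  peak·(1 − fatigue/100), mid-point chosen so the 30-s average matches MP,
  clamped to keep the curve monotone) are attached per subject.
* **Not emulated:** VO₂ on-kinetics and the slow component, substrate-driven
  RER drift, cadence/biomechanics, day-to-day variability, measurement
  artifacts (mask leaks, swallowed breaths). Passing tests therefore show
  that the *algorithms* recover known structure under realistic noise — not
  that the physiological claims hold in real athletes.

## 8. Numerical choices and degenerate inputs

* OLS everywhere is unregularized; singular consensus designs raise a
  rank-deficiency error naming the offending features.
* Greedy ties (equal SSE reduction) go to the lower column index;
  stability-vote ties to the earlier mean selection position, then index.
* Split sizes follow largest-remainder rounding globally and within each
  stratum (each stratum deviates from the global fractions by at most one
  subject); cohorts too small to populate three strata fall back to a
  single stratum.
* Spearman is computed from average ranks and clipped to [−1, 1]; constant
  predictions are flagged rather than scored.
* All randomness flows from explicit seeds; reports contain no timestamps,
  so identical configurations give byte-identical output bundles (hashes of
  the configuration are embedded in every artifact).

## 9. Problem sizes used in the shipped checks

The test and acceptance suites run at deliberately scaled sizes chosen as
package defaults: cohorts of 20–88 subjects, stability voting at 50–200
runs and the outer protocol at 20–80 repeats (against the method defaults of
1000 × 100), 100-replicate recovery sweeps for the greedy oracle and the
V-slope noise study, and 20 seeded graphs for the exhaustive modularity
comparison. The method defaults remain 1000 voting runs × 100 outer repeats
and are what the CLI uses unless configured otherwise.

## 10. Known limitations

* The registry's provisional formulas (section 2) are reasoned readings of
  ambiguous names, not authoritative definitions; the override hook exists
  precisely because a lab may define them differently.
* The stop rule's behaviour depends strongly on n: with small training sets
  and high planted R² it seldom fires (section 5), so consensus equations
  are denser than the published six/four-feature examples.
* Signed correlation networks are out of scope (edge weights are |ρ|);
  alternative community algorithms (Louvain, etc.) are deliberately not
  provided.
* The simulator's linear-ramp VO₂ model cannot probe protocols whose
  features depend on kinetics (e.g. slow-component-sensitive measures).
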