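# Methods

`glucowear` re-implements, end to end, a blood-glucose forecasting pipeline
for free-living wearable data: a continuous glucose monitor (CGM) sampled
every 5 minutes, change-triggered smartwatch sensor streams (heart rate, step
detector, four motion sensors), and a manually kept eat/drink log. Because no
real cohort ships with the package, a synthetic generator stands in for the
data source; every downstream stage (consolidation, fusion, forecasting,
evaluation) treats its output exactly as it would treat real exports.

## Synthetic physiology

Latent glucose follows a minimal mechanistic stochastic ODE, integrated by
Euler steps at 1 s:

    dG/dt = -k_clear (G - G_b) + k_meal M(t)
            - [k_now E(t) + k_late E(t - Δ)] (G - G_floor) + σ ξ(t)

* `M(t)` — carbohydrate appearance, a gamma(shape 2) rate
  `C (t-t0)/τ² exp(-(t-t0)/τ)` per meal; `τ = 40 min`. `k_meal` is calibrated
  in closed form so a 60 g meal peaks ≈ 70 mg/dL above baseline.
* `E(t)` — step rate smoothed with a 15-min exponential window.
* Exercise acts through two pathways: a modest uptake during the bout
  (`k_now = 0.01 /min` per step/s) and a larger one delayed by a dead time
  `Δ = 40 min` (`k_late = 0.03 /min` per step/s). The delayed pathway models
  glycogen repletion — the mechanism behind delayed post-exercise
  hypoglycemia — and is what makes heart-rate/step history genuinely
  predictive of future glucose: a dead-time effect is invisible to the CGM
  trace until it begins, whereas a smoothly lagged effect is fully encoded in
  the current CGM slope. (An earlier single-pathway variant was discarded for
  exactly that reason: an oracle linear probe showed step/heart-rate features
  added nothing beyond glucose slopes.)
* Defaults: baseline 95 mg/dL, clearance 0.01 /min, floor 40 mg/dL, process
  noise 0.4 mg/dL·min^-1/2, CGM noise 2 mg/dL, resting HR 65 bpm,
  HR gain 55 bpm per step/s, walking cadence 1.7 steps/s, 3 meals and
  1 exercise bout per 12-h wear day, carbs uniform on 30–90 g.
* Drinks (25% of meal events) carry carbs with probability 0.5, encoding that
  a logged drink need not contain carbohydrate; each eat/drink interval is
  omitted from the log with probability `activity_dropout_p` (default 0.3).

Recording artifacts emulated: CGM fires every 300 s day and night; watch
sensors emit only inside the wear window (08:00–20:00) and only when a
value changes (heart rate on integer-bpm change, one step-detector event per
step, motion sensors as uninformative noise streams every ~6 s); overnight is
total watch silence. Randomness is split per (participant, day) with
counter-based seed sequences so extending a simulation never perturbs
earlier days.

What the generator does **not** model: insulin dosing and β-cell dynamics,
meal composition beyond total carbs, CGM drift/dropout/compression artifacts,
mis-timed activity logging, circadian variation in insulin sensitivity.
Passing tests on this generator therefore demonstrate that the pipeline
recovers the relationships the generator encodes — not that the same effect
sizes would be observed in a real cohort.

## Ingestion and fusion

Change-triggered events are consolidated into complete per-timestamp records
by carrying each state sensor's last value forward; the step detector is an
impulse (a per-timestamp count, never forward-filled — forward-filling would
fabricate steps). Piecewise aggregate approximation collapses each state
channel to the time-weighted mean of its piecewise-constant trace per second;
glucose is imputed to 1 Hz by zero-order hold (interpolation would use a
future CGM point); activities map to labels 0/none, 1/eat, 2/drink, the
later-starting interval winning overlaps and ties breaking to drink.

Wear segments are maximal runs with all required channels present and no
sensor silence above 10 s. Sliding observation windows (W ∈ {30, 60, 90} min
of history) are cut inside single segments with a 300 s default stride,
phase-aligned so each target — glucose H ∈ {5, 10, 15, 30, 45, 60} min past
the window end — coincides with an actual CGM measurement; targets stay in
raw mg/dL. Inputs are min–max scaled per channel with statistics fit on the
training split only, out-of-range values clipped to [0, 1] and constant
channels mapped to 0. On a segment of L seconds the window count is
`floor((L - 60(W+H))/stride) + 1` when targets are unconstrained; CGM
phase alignment can remove at most one window.

## Forecasting

The forecaster is a from-scratch Rocket regressor: K random dilated
convolutional kernels (length ∈ {7, 9, 11}; a random channel subset; weights
standard normal, mean-centred per channel; bias uniform on [-1, 1]; dilation
`floor(2^a)` with `a ~ U[0, log2((T-1)/(l-1))]`; zero padding of half the
span with probability 1/2), each pooled into two features — PPV (proportion
of positive convolution outputs) and max — and a closed-form ridge regression
from the 2K features to the target. Features are standardised with
training statistics; near-constant features are floored at
`1e-2 (1 + |mean|)` rather than divided by a vanishing standard deviation
(otherwise a feature that is constant on the training fold but not on the
test fold produces unbounded standardised values), and exactly constant
features pass through as zeros. The ridge system `(ZᵀZ + αI)β = Zᵀy` is
solved through one SVD for the whole penalty grid (10 log-spaced candidates
in [1e-3, 1e3]); α is chosen by RMSE on chronological contiguous inner
validation blocks, and the intercept is the training-target mean. Identical
seed and data give bit-identical predictions; models serialise to a JSON
header plus flat binary coefficient block and round-trip exactly.

Baselines behind the same fit/predict interface: persistence (last observed
window glucose — the strongest naive CGM forecaster) and an ordinary
least-squares autoregression on the last `order` CGM ticks.

## Evaluation

RMSE in mg/dL, plus Clarke Error Grid Analysis using the canonical 1987
piecewise-linear zones; Zone A is a relative deviation of at most 20% (bound
inclusive) or both values inside the hypoglycemic range (< 70 mg/dL); the
hypoglycemic clause requires *both* values below the bound. Zone order of
precedence is A, E, C, D, else B.

Because windows overlap in time, random K-fold would leak; generalisation is
estimated with chronological blocked nested cross-validation: contiguous
outer test blocks (default 5), a purge gap of max(W, H) minutes around each
block, and contiguous inner blocks (default 3) for penalty selection. The
experiment runner evaluates every (participant, model, channel combination,
W, H) cell and reports mean fold RMSE, fold-level RMSEs and pooled EGA zone
counts; cells with too few windows are recorded as missing. Aggregation
across participants is the unweighted mean; report ties break to the smaller
observation window.

## Replicate study (desk scale)

`replicate_ablation_study` re-runs the channel-ablation and model-comparison
contrast on seeded synthetic cohorts: per seed, 2 participants × 5 days,
W = 60 min, H ∈ {30, 60} min, activity logging at 50% dropout with drink-carb
uncertainty on. Problem sizes are chosen for a single-core desk run: 250
kernels, the default 300 s window stride, 3 outer folds, per-participant min–max scaling
over all of that participant's windows (the fold-wise alternative multiplies
the transform cost by the fold count), one kernel transform shared between
the two horizons, and common kernel seeds across channel combinations so the
comparison is paired. The activity arm runs on the first 10 seeds. These
sizes are roughly 40× smaller in kernels × windows than the best published
setting of the method (100 000 kernels); contrasts whose effect size is small
relative to seed-level noise at this scale are reported as such by the test
suite rather than being tuned into significance.

## Numerical choices and edge cases

* Euler step 1 s everywhere (matches the 1 Hz pipeline cadence; stable for
  all default rates; a 0.1 s reference integration agrees to < 1% on meal
  excursions).
* Glucose is clamped at 1 mg/dL inside the integrator; non-finite states
  abort with a diagnostic.
* Consolidation rejects unsorted input; simultaneous events merge with last
  parse order winning per sensor.
* CGM readers reject duplicate timestamps (device re-uploads) rather than
  silently deduplicating, and sort out-of-order rows.
* Predictions are clipped to [1, 400] mg/dL for EGA classification only;
  RMSE uses unclipped values.
* Empty experiment cells (too few windows for the fold plan) are missing
  values, never errors.

## Known limitations

* The generator's effect sizes are choices, not estimates from data; the
  replicate study demonstrates pipeline correctness and direction of effects,
  not clinical effect sizes.
* Min–max scaling fit per participant over all windows (used in the replicate
  study for tractability) leaks range information across time; the fold-wise
  scaler used by `evaluate_cell` is the leakage-free default and is what the
  no-leakage audit exercises.
* Motion channels are uninformative by construction, so the pipeline cannot
  be used to test whether real motion data would help.
* The activity channel of the generator is perfectly timed when logged;
  real manual logs are also mis-timed, which plausibly further reduces their
  value.
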