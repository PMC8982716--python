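# Methods

This note documents the models, numerical choices and study designs
implemented in `cgmdrnn`, and what the synthetic experiments do and do
not show about real CGM data.

## The forecasting problem

A CGM sensor reports interstitial glucose every 5 minutes (288 samples
per day). The task is sequence-to-one regression: from the last hour of
multi-channel history — glucose G (mg/dL), insulin bolus I (units), meal
carbohydrate M (g) and a time-of-day index T ∈ [0, 1) — predict the
glucose level 30 minutes (6 slots) ahead. The network regresses the
*change* ΔBG = G(t+6) − G(t) and the forecast is ŷ = ΔBĜ + G(t), so an
untrained (zero-head) model degrades gracefully to the persistence
forecast.

## The dilated recurrent network

Each layer is a vanilla tanh cell whose recurrent edge skips d−1 steps:

    h_t^l = tanh(W_rec h_{t−d_l}^l + W_in h_t^{l−1} + b^l)

with layer dilations (1, 2, 4), hidden width 32, input width 4 and
sequence length 12. Only the top layer's final state feeds an affine
head (no output nonlinearity). Parameter count per vanilla state is
n² + m·n + n (an LSTM cell would cost 4×, a GRU 3×; `param_count`
implements the accounting, the cells themselves are an extension point).

Design choices where the architecture description is open:

- **Layer-to-layer connectivity.** Dilation affects only the recurrent
  edge; layer l consumes layer l−1's output at the *same* timestep.
  This reading is pinned by a test: with all dilations set to 1 the
  network must agree with an independently coded stacked RNN to 1e−10.
- **Pre-window states** are zero vectors wherever t − d < 1.
- **Initialisation.** Uniform(−1/√fan_in, 1/√fan_in) for input and
  recurrent weights (both treated uniformly), zero biases, zero head;
  seeded.

Forward and backward passes are explicit numpy backpropagation-through-
time. Gradients are verified against central finite differences (worst
relative error ~1e−9 in float64). Experiments train in float32 for
speed; the numerical tests run in float64.

## Training

Mean squared ΔBG error, RMSprop (learning rate 0.001, decay 0.9,
epsilon 1e−8, no momentum), mini-batches of 512 drawn by a per-epoch
seeded shuffle, global-norm gradient clipping at 5.0 (vanilla-RNN
gradient explosion is the known failure mode dilation alleviates but
does not eliminate), early stopping on validation RMSE (default
patience 10, epoch cap 200), returning the best-validation snapshot.
The validation set is the chronological tail (10%) of the training
windows — time series are split chronologically, never shuffled across
the train/validation boundary, so a 90/10 train/test partition followed
by the 90/10 validation split yields 81/9/10 overall.

**Two-phase transfer learning.** Phase 1 trains a generalised model on
a corpus that doubles the target's record: the first half is all of the
target, the second half is split equally among five donors (each thus
contributes 10% of the combined corpus). Each donation is the *final*
contiguous block of the donor's record — a deterministic rule chosen
because the sampling rule is otherwise open. Phase 2 fine-tunes all
weights (no freezing) on the target alone with the same early-stopping
rule (default cap 50 epochs). Windows never cross corpus-piece
boundaries, and one scaler (fitted on the phase-1 training windows) is
used in both phases so the weights see a consistent input scale.

## Baselines

All baselines consume the same windows and the same test-time data
path, so metric differences isolate the predictor.

- **ARX(3)**: ordinary least squares of the absolute future value on
  the last 3 lags of all four channels plus an intercept (13
  coefficients). Realised as lagged least squares rather than a
  system-identification toolbox call; rank-deficient designs fall back
  to the minimum-norm solution and are flagged.
- **NNPG**: three fully connected layers (64 and 32 tanh units, linear
  output — widths chosen for capacity comparable to the recurrent
  model) on the flattened 48-feature window, trained on ΔBG with the
  same optimizer contract, learning rate 0.001 and batch size 32.
  Predicting ΔBG rather than the absolute level keeps the comparison
  with the other methods like-for-like.
- **SVR**: scikit-learn's epsilon-insensitive RBF support-vector
  regression, C = 100, γ = 0.01, epsilon 0.1 on standardised ΔBG
  targets.

## Evaluation statistics

- **RMSE** (mg/dL): √(mean (ŷ − y)²) over aligned forecast/actual pairs.
- **MARD** (%): mean |ŷ − y| / y × 100; actual values must be positive
  (guaranteed by the series invariant); non-positive actuals are an
  error, never silently dropped.
- **Time lag** (min): the delay maximising the cross-correlation
  between forecast and actual series. The raw cross-correlation is
  unnormalised and amplitude-dominated, so Pearson correlation of the
  overlapping segments is used at each integer shift δ ∈ [0, 6]; the
  arg-max is refined by parabolic interpolation through the peak and
  its neighbours, giving the sub-slot (fractional-minute) resolution
  per-subject lags require. The search is restricted to [0, PH]: a
  forecast cannot lead its target. Zero-variance series make the lag
  undefined (an error). The refinement is validated against a
  100×-oversampled dense-grid oracle.
- **Paired two-sided t-test** between per-subject metric vectors
  (scipy); zero-variance differences are reported as p = 1 with a
  degenerate flag rather than raised mid-pipeline.

## The synthetic cohort generator

Real CGM corpora are distributed under data-use agreements, and the
FDA-accepted virtual-patient simulator is licensed, so this package
ships its own documented generator: a Bergman-style minimal model with
two-compartment gut absorption (meals) and two-compartment subcutaneous
insulin absorption (boluses), integrated by fixed-step RK4 at a
1-minute internal step and subsampled to the 5-minute grid (fixed-step
integration keeps the output bit-reproducible and free of adaptive-
solver dependence). Defaults describe a ~70 kg adult with T1DM-like
insulin sensitivity; with them a 50 g meal raises glucose by roughly
+170 mg/dL unbolused and ~+100 when bolused, day-long traces span
roughly 50–330 mg/dL with mean ≈ 150, and the per-5-min step never
exceeds ~25 mg/dL. All rates must be positive; violations are
configuration errors.

Event statistics: 3 meals/day (anchors 7:30, 12:30, 18:30) with size
CV = 10% and timing SD = 20 minutes (the timing spread is in minutes —
the conventional unit for meal-time variability); 1–5 boluses/day drawn
uniformly, timed near (but not forced onto) meal times, sized from the
day's carbohydrate total via a 10 g/U carb ratio with a Dirichlet
split. Sensor noise is additive Gaussian AR(1) with ρ = 0.7 and
marginal SD 2.5 mg/dL — CGM noise is autocorrelated, not white.
Exercise is not modelled (it is not an input channel).

Clinical-style defects are injected by separate, seeded operations:
missing intervals (mask cleared), additive spikes (binomially placed,
Gaussian magnitude, audit trail of spike amounts returned), and frozen
readings (a stuck value for a default 2 h, mask left valid because the
defect is undetectable from the mask).

**What the generator does not emulate:** illness, stress, exercise,
manual-reporting errors in meal sizes, sensor drift/recalibration
steps, and the inter-subject parameter distributions of a validated
virtual-patient population. Passing the cohort experiments therefore
shows the pipeline learns the simulated meal/insulin dynamics better
than the baselines under controlled conditions; it does not certify
clinical accuracy on real patients.

## Preprocessing

Training-time: maximal invalid runs (mask false or glucose ≤ 0 — the
clinical convention of literal 0 readings) are detected; gaps of at
most 24 slots (2 h) are filled by the straight line between bounding
valid samples — longer fills would fabricate physiology, so longer gaps
instead split the record into independent segments that windows never
cross. A centred running median (default window 5 slots = 25 min,
shrinking symmetrically at the edges) removes 1–2-slot spikes without
flattening meal peaks. Gap boundaries follow the convention that a gap
"between A and B" covers the slots strictly after A through B.

Test-time the future is unknown, so missing stretches are instead
estimated causally by a least-squares line through the last k = 6 valid
samples (30 min of trend; k = 2 degenerates to slope continuation;
fewer than 2 valid points fall back to hold-last-value with a flag).

Interpolation runs before the median filter; every touched slot can be
logged as a JSON-lines audit trail.

## Windowing

Stride-1 sliding windows of 12 steps with the label 6 slots ahead; a
window is kept only if all its slots and its target lie in one
contiguous valid run of one subject, so no input can postdate its
label and no window mixes subjects. G, I and M are standardised with
training-set statistics (tanh recurrences saturate on raw mg/dL
magnitudes); the time channel already lives in [0, 1) and passes
through; labels and the stored current glucose stay in mg/dL.
Zero-variance channels are mean-shifted with scale 1. Bolus and meal
channels hold the event quantity at the administration slot and zero
elsewhere (no smearing). Per-epoch mini-batch order is a seeded
shuffle, reproducible per (seed, epoch) and switchable off.

## Study designs and problem sizes

- **Cohort benchmark** (`run_cohort_benchmark`): 5 subjects × (30 days
  train + 5 days test), per-subject models, 3 seeds, median of
  subject-mean metrics. The dilated RNN trains with epoch cap 150 and
  patience 25, at which point validation RMSE has plateaued on this
  generator's output; ARX is a closed-form fit. Per-subject physiology
  varies by 10% lognormal jitter on the rate constants.
- **Transfer experiment** (`run_transfer_experiment`): one target with
  8 days of data, five donors with 8 days each, donors sharing the
  target's physiology (only event realisations differ) — the regime
  where borrowing data should help. Transfer (15 + 10 epochs) is
  compared with from-scratch training at the same 25-epoch total on
  the target's own validation split, median over 5 seeds.

Desk-scale sizes were chosen once as the smallest cohort at which the
across-seed medians are stable; the full-year scale (360 days,
103,680 slots per subject) is exercised for generation and windowing
but not for training.

## Known limitations

- The simulator is a minimal model, not a validated patient simulator;
  absolute error magnitudes on it are not comparable to clinical data.
- LSTM/GRU cells are an extension point; only their parameter
  accounting is implemented.
- Training is CPU-only and sequential; the dilated chains' parallel
  evaluation is not exploited (correctness over throughput).
- The OhioT1DM-style XML reader is provided for interoperability but is
  exercised only on synthetic fixtures; that corpus requires a
  data-use agreement.
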