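# Methods

This note records the model, the defaults and the judgement calls behind
`aeronose`, in the order data flows through the pipeline.

## Synthetic recordings

The generator emulates one headspace sampling cycle of a portable
chemiresistive e-nose: `T = Σ(phase durations) × sampling rate` rows by `S`
sensors of resistance in ohms. Defaults: phases (15, 50, 5, 20) s at 1 Hz
(`T = 90`), `S = 32`, 8 classes × 9 replicates.

Each class is a `ClassProfile`: a per-sensor vector `delta` of maximal
fractional resistance changes (positive or negative, clipped to ±0.5) plus
first-order rise and decay time constants. The noise-free envelope is

- baseline phase: `R = B`
- sample draw-in: `R = B·(1 + delta·(1 − exp(−(t − t₁)/τ_rise)))`
- from snout removal on: first-order return toward `B` with `τ_decay`,
  starting from the value reached at the end of draw-in,

with `B` the baseline level (default 10 kΩ). First-order kinetics is the
standard small-signal model for absorption/desorption on conducting-polymer
composites and matches the qualitative baseline → rise-to-plateau →
recovery shape of real cycles. On top of the envelope: additive Gaussian
noise with σ = `noise_sd · B` (default 0.75 % of baseline — the scale of
visible channel noise on commercial arrays) and a linear drift
`B · drift_slope · t` (default 1e-5 /s).

Class signatures share a common base pattern and diverge by
`class_separation × delta_scale` (defaults 1.0 × 0.15) along unit-norm
random directions, so the expected pairwise signature distance is linear in
`class_separation` and zero separation collapses all classes. One pair of
classes (default the last two) is drawn at 15 % of the normal divergence to
emulate instrumentally overlapping aroma profiles. Rise/decay constants are
drawn per class from 5–10 s and 8–15 s. The humidity-sensitive channels
{5, 6, 23, 31} (1-based) receive a class-independent signature, so
excluding them is meaningful rather than cosmetic.

Determinism: per-file seeds derive from
`SeedSequence([master_seed, class_index, replicate])`, documented in
`synthetic.replicate_seed`, so a single recording can be regenerated
without the rest of the dataset.

What the generator does **not** emulate: VOC chemistry, cross-cycle drift
memory, humidity/temperature covariation, non-Gaussian or multiplicative
noise, and sensor-specific calibration curves. Tests passing on this
generator demonstrate the pipeline's correctness and its behaviour under
controlled separability/noise, not performance on real malt headspace data
(which is not publicly deposited).

## Conditioning

- Channel exclusion precedes everything; smoothing is a trailing rolling
  mean (default window 5 samples; no window is canonical in the field, so
  it is configurable) with truncated partial windows so the output length
  equals the input length.
- Local normalization takes `R0` as the **mean over the baseline phase**
  rather than a single first sample — a lower-variance estimator of the
  same quantity; the window is configurable.
- Both schemes apply an absolute value in the numerator, so channels whose
  resistance *decreases* on exposure still map to positive responses, and
  outputs land in `[0, 1]` by construction.
- Flat (zero-range) channels are zeroed with a logged warning instead of
  raising, so a degenerate channel cannot abort a batch.
- The global scale is fitted on **training data only** and reused on test
  and hold-out recordings, with out-of-range values clipped to `[0, 1]`
  and counted in the log. This avoids leaking test extremes into the
  per-sensor ranges; normalization spans the full 90 s cycle.

## AERO encoding

Amplitude is quantized to `floor(x · 2^n)` clipped to `2^n − 1` (default
n = 4 → 16 levels). The encoder emits exactly one event per
(sensor, timepoint), ordered by (t, sensor); level-0 events stay in the
stream for timestamp bookkeeping but are excluded from the activation-bin
set the classifier learns from — baseline-level samples carry no
discriminative amplitude. The flattened bin layout
`((sensor_pos · T) + t) · levels + level` is fixed and versioned
(`aeronose-bins-v1`) so saved models are portable across sessions.

The per-neuron weight capacity is validated against `2 × T × levels`
(2880 at T = 90, 16 levels). The factor 2 is honoured as a validation
bound only; the input space itself has `S × T × levels` bins and no
polarity channels are created.

## Learning rule

The on-chip rule this re-creates is proprietary; the implementation is a
faithful behavioural model with every scalar given an explicit role:

- **Match ratio** `m = potential / min(W, |bins|)` decides reinforce vs
  recruit against the `learning_competition` threshold.
- **Reinforcement** removes at most `ceil(plasticity · W)` synapses *not*
  in the current sample's bins (never one that matches) and replaces them
  with unclaimed active bins, never exceeding `W`; plasticity then decays
  multiplicatively, `p ← max(p_min, p·(1 − plastic_decay))`, so after `k`
  reinforcements `p = max(p_min, p₀(1 − d)^k)`.
- **Recruitment** wires a fresh neuron to a seeded random subset of the
  sample's bins of size `min(W, |bins|)`; if the pool is exhausted the
  best used neuron reinforces regardless.
- Learning is **label-gated**: only the true class's pool competes for a
  sample. The readout uses class pools and labels, so this mirrors
  edge-learning practice even though the underlying rule is often described
  as unsupervised; a fully unsupervised mode (all neurons compete, labels
  assigned post hoc by majority) is available behind `supervised=False`.
- All ties — learning winner and WTA readout — break to the lowest neuron
  index, and the per-event RNG is seeded from (model seed, event counter),
  making any (seed, presentation order) pair bit-reproducible.
- The readout is pure argmax; an optional `firing_threshold` floors
  sub-threshold potentials to zero before the argmax for users who want a
  reject behaviour, but it is off by default.

Defaults for the six parameters — 10 neurons/class, 1795 weights/neuron,
initial plasticity 0.84, learning competition 0.48, minimum plasticity
0.21, plastic decay 0.27 — are the optimized operating point for the
90-timepoint, 4-bit, 8-class setting.

## Optimization

Fitness is stratified 5-fold CV accuracy; "stable" accuracy is read as the
fold mean minus `λ ×` (fold standard deviation) with `λ = 0` by default
(the penalty is exposed because the notion is ambiguous). The search is
classic rand/1/bin differential evolution — population 15, F = 0.6,
CR = 0.8, 25 generations by default, all configurable — with integer
parameters rounded after mutation, candidates clipped to the bounds, and
the best individual ever evaluated returned. Both a DE and a small
grid-search entry point exist, since either is a defensible way to obtain
the published operating point; the package does not privilege one.

## Evaluation

Stratified k-fold splitting, the hold-out split (per-class floor rounding:
9 replicates at 0.7 → 6 train / 3 test) and the confusion matrix are
delegated to scikit-learn behind the package's interfaces. Static features
are per-sensor max response, rectangle-rule AUC (`sum × dt`), and maximal
forward first-difference over the sniffing phase including the transition
into it (so an onset step of height 1 yields slope `1/dt`; the estimator
for "slope" is otherwise unspecified in the field). Baselines are
standardize → PCA(3) → {LDA, RBF-SVM with C = 1, distance-weighted 5-NN};
the classifier hyperparameters are conventional defaults and configurable.
Accuracy variance is reported as the ± spread of fold accuracies, and the
global normalization scale is refitted inside every CV fold on that fold's
training data.

## Problem sizes

The default experiment (72 recordings of 90 × 32, five folds plus hold-out
plus baselines) completes in a few seconds on one core; the test suite's
property checks use 3-class, 10–12-sensor datasets and the acceptance-style
end-to-end check averages five master seeds of the full 8 × 9 protocol.
These sizes were chosen as the smallest that still exercise every code
path and the stated statistical properties.

## Known limitations

- Spike timing within a timepoint, refractoriness, leak dynamics and
  multi-layer topologies are out of scope; the potential is a plain
  coincidence count.
- The synthetic conditions are favourable by design (the default
  separation yields near-perfect accuracy); absolute accuracies are
  properties of those conditions, not estimates for any real dataset.
- Global normalization assumes the training extremes bracket future data;
  heavy drift would erode that and the clipping counter is the only
  diagnostic.
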