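# Methods

## Data model

A subject is a set of visits at (possibly off-schedule, fractional) months,
each carrying a 23-variable record: one categorical diagnosis (NC/MCI/AD,
one-hot encoded as three value columns) and 22 continuous markers.  Visits
are assigned to a regular grid of 1-, 3- or 6-month slots by nearest-slot
rounding (half-way points round to even, numpy's default); the subject's
first visit defines month 0.  When two visits collide on one slot, each
observed feature is taken from the visit nearer the slot centre (ties go to
the earlier visit) and features observed in only one visit are merged, so
no observation is discarded unless the same feature is observed in both.
The observation mask is carried separately from the values and is never
modified by imputation, so losses and metrics only ever touch truly
observed entries.

Continuous markers are z-normalized with means and standard deviations
estimated on training subjects' observed entries only; validation and test
data reuse the training statistics.  Normalize-then-denormalize is the
identity to numerical tolerance.

## Recurrent cells

The minimal gated cell uses a single forget gate:
u_t = tanh(W_u x_t + b_u); f_t = σ(U_h h_{t−1} + U_u u_t + b_f);
h_t = f_t ⊙ h_{t−1} + (1 − f_t) ⊙ u_t.  Since f_t ∈ (0,1) and |u_t| ≤ 1,
the state is a coordinatewise convex combination and ‖h_t‖∞ ≤
max(‖h_{t−1}‖∞, 1): the cell is intrinsically stable under arbitrarily long
recursion.  The exact placement of the gate's dependence on u_t (rather
than on x_t directly) follows the original minimal-RNN formulation.

The linear state-space (LSS) cell is the gate- and nonlinearity-free
counterpart h_t = A h_{t−1} + B x_t + b with the same output heads
(softmax retained on the diagnosis head so probabilities stay valid).
Because the linear cell has no squashing nonlinearity, two numerical
safeguards keep its closed loop usable:

- **Transition-norm projection** (`max_transition_norm`, default 1.0): after
  each Adam step, A is rescaled if its largest singular value exceeds the
  cap, so the open-loop dynamics cannot diverge.
- **Feedback clipping** (`feedback_clip`, default 8 z-units): continuous
  predictions fed back as inputs — during model filling and recursive
  forecasting — are clipped to ±8 standard deviations.  Real markers live
  well inside that range, and the bound makes the prediction-to-input loop
  (through the output heads) bounded for any cell.  The clip is treated as
  a hard saturation in the backward pass (zero gradient where active).
  Both safeguards also apply nominally to the gated cell, where they never
  bind.

LSS initialization is a damped near-identity (A = 0.5 I + noise, small B);
a plain Glorot start lets hidden-state norms grow with sequence length and
saturates the softmax head, which measurably slows learning.

Layers can be stacked (1–3): layer ℓ's hidden state is layer ℓ+1's input at
the same timestep, and the output heads read the top layer.

## Loss and training

The loss sums, over timepoints t ≥ 2, the cross-entropy of the observed
diagnosis plus the mean absolute error of observed continuous entries,
the two terms weighted equally.  The MAE term divides by the constant
number of continuous variables (22) rather than the per-timepoint observed
count; the normalizer only scales the loss and moves no optimum.  Missing
entries contribute nothing: perturbing a masked value never changes the
loss (verified by 10³ random perturbations in the tests).

Training uses Adam (β = 0.9/0.999) on whole-subject sequences, batched with
padding and validity masks; h₀ = 0.  All gradients are hand-derived
reverse-mode and checked against central finite differences to ~1e-7
relative error, including through model-filled inputs and stacked layers.
Input dropout is resampled per timepoint; recurrent dropout uses one mask
per sequence (variational style) applied where the previous state enters
the gate pre-activation, leaving the convex-combination path — the cell's
memory — undropped.  An optional multiplicative per-epoch learning-rate
decay and warm-starting from existing parameters (`init_from`) support
annealing schedules.  With a validation cohort, the parameters with the
lowest validation loss (checked every `val_every` epochs) are kept;
validation loss is used here rather than a full forecast-based composite
because it needs no rollout per check, while the hyperparameter search
(below) does select on forecast metrics.  A non-finite loss aborts with a
message advising a lower learning rate.  Training is bit-deterministic
given the config seed.

## Missing-data strategies

- **Forward filling**: last observation carried forward per feature;
  leading gaps take training fallback values (pooled marker means; the
  empirical class-frequency 3-vector for diagnosis).
- **Linear filling**: interior gaps interpolated per feature; trailing gaps
  forward-filled; leading gaps mean-filled.  Diagnosis is interpolated on
  its one-hot coordinates, producing soft 3-vectors; a `hard_diagnosis`
  flag switches to carrying the last label instead.
- **Model filling**: during the forward pass, a missing input at step t is
  replaced by the model's own prediction from step t−1 (first-visit gaps
  are mean-filled).  Gradients flow through filled values by default; a
  stop-gradient switch exists for ablation.  On feature-complete data,
  model filling is exactly teacher forcing — equal losses and gradients —
  which the tests assert to 1e-12.

Filling operates on z-normalized values, so the continuous mean-fill value
is 0; this is equivalent to mean-filling in natural units with one code
path.

## Forecasting and evaluation

Forecasts consume the input visits (gaps filled per strategy), then
autoregress one grid step at a time; grid-step predictions are linearly
interpolated to monthly resolution (diagnosis vectors renormalized after
interpolation) and continuous markers mapped back to natural units.
Ventricular volume is scored as ventricles/ICV, both taken from the
model's predictions; ground-truth ratios use visits where both are
observed.

Metrics: mAUC is the unweighted mean of the three one-vs-rest rank AUCs
(ties count one half; a class absent from the labels is dropped with a
warning); BCA averages (sensitivity + specificity)/2 over classes on argmax
assignments; MAE averages |error| over observed future entries.  Group
breakdowns stratify subjects by (diagnosis at last input visit → diagnosis
at last visit) into NC-S/NC-P/MCI-R/MCI-S/MCI-P/AD, score diagnosis by
plain accuracy (single-class strata make ranking metrics undefined) and
exclude AD reverters and subjects lacking an observed diagnosis in either
half.  Yearly breakdowns bucket target months 1–12, 13–24, … relative to
the last input month.

The corrected resampled t-test uses
t = mean(d) / sqrt((1/K + n_test/n_train)·var(d)) with K−1 degrees of
freedom, with subject counts for n_train/n_test; it reduces to the
classical paired t-test as n_test/n_train → 0.  Multiple comparisons use
Benjamini–Hochberg step-up at q = 0.05 (via statsmodels).

## Benchmark protocol

Subjects are permuted once per master seed and partitioned into K disjoint
test blocks (default K = 20) tiling the cohort; per repeat the remaining
subjects split 18:1 into train and validation.  Validation/test subjects
contribute the first ⌈V/2⌉ visits as input and the rest as targets;
single-visit subjects have no targets and drop out of metric denominators.
Hyperparameters are tuned per split by seeded random search over the
published ranges (dropout uniform on [0, 0.5]; L2 10⁻⁷–10⁻⁵ and learning
rate 10⁻⁵–10⁻² log-uniform; 1–3 layers; hidden 128–512; SVM/SVR kernel
linear/RBF, penalty and gamma 10⁻³–10³, epsilon 10⁻³–1), selecting on a
validation composite of mAUC minus scale-normalized MAE terms.  Random
search replaces a surrogate-based optimizer as the reproducible, seedable
equivalent over identical ranges.  Result files embed the config hash,
master seed and package version, and a fixed master seed reproduces
byte-identical reports.

## SVM/SVR harness

Static models require fixed-length inputs, so subjects are regridded to
6-month slots, linear-filled, and featurized by concatenating the 23
variables over k ∈ {1,…,4} trailing slots (diagnosis as an ordinal code
0/1/2 in the design vector).  Separate models per target × k × horizon
(6…60 months) give 120 cells; training samples take every window whose
target slot holds an actual observation (a 10-visit subject yields 9, 8, 7
samples at 6-, 12-, 18-month horizons with k = 1).  The diagnosis SVM emits
pairwise-coupled class probabilities so mAUC is computable; regression
targets (ADAS-Cog13 on the z-scale, ventricles/ICV in natural units) are
standardized per cell before fitting.  At prediction time the largest
feasible k′ ≤ k is used for short subjects, predictions are interpolated to
monthly resolution and forward-filled past month 60.

## Synthetic cohort generator

Each subject follows a monotone latent stage z(t) = logistic(ρ·(t + t₀))
with per-subject onset offset t₀ ~ N(−25, 45²) months and log-normal rate ρ
(median ≈ 0.022 logits/month).  Markers are affine links of the stage
anchored at the population mean at z = 0.5, spanning about ±1 SD in the
clinical direction (cognitive scores and ventricles worsen upward,
volumes and FDG downward, ICV stable), plus a per-subject intercept
(0.4 SD) and visit noise (0.25 SD).  Diagnosis thresholds a noisy copy of
the stage (noise 0.15) at z = 0.35/0.65 with 0.08 hysteresis, so forward
transitions dominate and reversions are rare but present; with all noise
zeroed the diagnosis sequence is exactly monotone.  Visit counts are drawn
from a rounded truncated normal whose location is solved so the truncated
mean equals the configured 7.3 (truncation at one visit would otherwise
inflate it); intervals are 6 ± 2 months.  Missingness is independent
Bernoulli per feature per visit with ADNI-like observed fractions (e.g.
diagnosis ~70%, MOCA ~39%, CSF ~19%); a block mode drops whole modalities
(CSF, PET, MRI, cognitive battery) per visit instead, emulating the
structural missingness of real studies.  Everything derives from a single
seed via split substreams, so cohorts are bit-reproducible.

What the generator does **not** emulate: ADNI's joint covariance beyond the
shared latent stage, site and scanner effects, informative dropout, and
visit-dependent missingness.  Passing tests on these cohorts therefore
demonstrate mechanical and statistical correctness of the pipeline and the
expected ordering of methods under MCAR missingness — not clinical-grade
performance on real data.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run, on one CPU in a few minutes:
generator calibration at n = 2000; the repeated-split benchmark on 100–200
subjects with 2–4 repeats and compact models (hidden 24–48, 10–30 epochs);
the model-fill versus forward-fill comparison on ten 300-subject cohorts
with 30% missingness (hidden 32, 25 epochs); and LSS recovery on 60
noiseless length-15 sequences with a staged learning-rate schedule
(3e-3 → 3e-5, ~1000 epochs at batch size 15).  These sizes are the
package's default demonstration scale; all of them are plain parameters
that scale up unchanged.

## Known limitations

- The LSS baseline's competitiveness depends on the stability safeguards
  above; with them disabled, long recursive rollouts can diverge.
- SVM probability estimates use Platt-style coupling, whose calibration on
  small strata is rough; mAUC is insensitive to monotone miscalibration.
- Under heavy, structured missingness (block mode) linear filling's soft
  diagnosis vectors are a modeling choice, not ground truth; the hard-label
  alternative is provided but not separately benchmarked.
- The equality-weighted two-term loss follows the reference protocol; no
  weighting sweep is included.
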