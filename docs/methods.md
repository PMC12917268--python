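# Methods

This note records the model, the parameter choices and their
rationale, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Pipeline overview

Raw multichannel EEG (256 Hz default) → zero-phase Butterworth
bandpass 0.05–75 Hz → segmentation into 2000-sample windows → a
13-value feature vector per window → bidirectional LSTM classifier →
ictal/interictal decision. The network's weights are trained by a
population metaheuristic maximising a validation classification
fitness; no gradients are computed anywhere.

## Preprocessing

A 4th-order Butterworth bandpass (0.05–75 Hz), applied
forward-backward (`sosfiltfilt`) so in-band components keep their
timing. The family and order are conventional choices for EEG
band-limiting; the passband corners are fixed design constants of the
pipeline. Filtering acts on the continuous record before
segmentation, avoiding per-segment edge transients.

Numerical note: the 0.05 Hz pole has a ~3 s time constant and rings
for tens of seconds. SciPy's default reflect-padding (a few dozen
samples) leaks that transient deep into the record, so the pad length
is set to `min(n−1, 10·fs/low_cut)` samples. Tests that probe the
steady-state in-band response measure ≥ 20 s away from record edges.

## The StFS feature set

Thirteen features per segment, ordered (spectral, Hjorth,
statistical).

**Statistical (5).** Skewness and kurtosis are the canonical
population moment ratios `m₃/σ³` and `m₄/σ⁴`; the median is the
standard sample median; σ uses population normalisation. Printed
variants of these formulas that are dimensionally inconsistent (a
skewness with an `(s−1)σ³` denominator, a kurtosis of raw fourth
powers, a median given as a rank position) were replaced by the
canonical estimators — the intent of the features (symmetry,
tailedness, central tendency, spread) is unambiguous.

**Hjorth (3).** Activity `var(U)`, mobility
`√(var(ΔU)/var(U))` and complexity `mobility(ΔU)/mobility(U)`, with
ΔU the first difference. The complexity is Hjorth's canonical ratio
form; a difference-of-ratios variant under a square root can go
negative and was not used.

**Spectral (5).** One-sided Hann periodogram (constant detrend),
restricted to the preprocessing passband, then centroid, spread,
skewness, kurtosis and crest (`max/mean`). Only the spread keeps an
outer square root (it is a standard deviation in Hz); wrapping the
other four in square roots would produce `√Hz`-type units. A
point-mass spectrum has zero spread, where the standardised
skewness/kurtosis are undefined and returned as 0.

**Degenerate segments.** A constant window supports neither moment
ratios nor a spectrum; it yields a flagged vector with zeroed
moment/spectral/Hjorth entries while mean, median and std remain
meaningful.

**Channels.** Features are computed per channel and averaged across
channels within a window; the class label is a property of the time
window, not the channel.

## Network input modes

The 13-feature table and a raw-window reading of the classifier input
are both supported, because the two are genuinely different designs:

- **features** (default for desk-scale work): the 13 values feed the
  BiLSTM as a 13-step scalar sequence, standardised column-wise with
  statistics frozen on the training portion.
- **segment**: the 2000-sample preprocessed window itself is the
  sequence, z-scored per window. This matches a sequence-input layer
  of width 2000 and is constructible at full scale (100 hidden
  units), but optimizer-driven training at that size is outside the
  test budget.

## Classifier

Standard LSTM cell per direction: input/forget/output gates are
sigmoids of `W·[h_prev, x_t] + b`, the candidate is a tanh of the
same form, `c_t = f⊙c_prev + i⊙c̃`, `h_t = o⊙tanh(c_t)`. The
backward direction runs the reversed sequence with its own
parameters. The classifier head concatenates the forward-final and
backward-final hidden states (mean-pooling over the concatenated
per-step outputs is available behind `NetworkConfig.pooling`) and
applies a dense softmax. Everything is float64; the sigmoid uses the
numerically stable piecewise form.

All parameters pack into one flat vector (per direction: gate weight
matrices in input/forget/candidate/output order, then biases; then
head weight and bias), tagged `bilstm-flat-1` in serialised models.
For hidden width H, scalar inputs and C classes the length is
`2·4·H·(1 + H + 1) + C·(2H + 1)` — 674 at H = 8, C = 2.

Dropout and gradient-descent hyperparameters from the reference
architecture's table are echoed in `RunConfig` metadata only; they
regularise backpropagation, which this package does not perform.

## Sparrow–cougar optimizer

A bounded continuous metaheuristic over a population of `e` rows of
dimension `k`. Each iteration:

1. Rows are ranked by fitness; the top `NP = 0.2·e` act as
   *producers*. One alarm value `T2 ~ U(0,1)` is drawn per iteration.
2. **Producer update.** If `T2 < R` (safety threshold, default 0.8):
   elementwise contraction `M ← M·exp(−u/(γ·i_max))` with rank `u`
   and fresh `γ ~ U(0,1]`. Otherwise the cougar hybrid: velocity
   `Vel ← Vel + q1·p1·(M_best − M)` (`q1 ~ U(0,1)`, constant
   `p1 = 2`), new position = the average of the noisy sparrow move
   `M + N·1` (scalar normal N) and the velocity move `M + Vel`.
3. **Scrounger update** for ranks `u > NP`. Starving rows
   (`u > e/2`): `N·exp((M_worst − M)/(γ·i_max))` elementwise with
   per-coordinate normal draws. Followers: `M_P + |M − M_P|·Q⁺·S`
   where `M_P` is the updated top producer, `Q` a random ±1 row,
   `Q⁺ = Qᵀ/k` its pseudoinverse and `S` the all-ones row — the
   product collapses to adding the signed mean absolute deviation to
   every coordinate, and reduces to `M_P + |M − M_P|` at k = 1.
4. **Danger group.** `⌈0.15·e⌉` random rows: a row worse than the
   best moves `M_good + γ·|M − M_good|`; a row at the best takes the
   escape step `M + X·|M − M_worst|/((m_u − m_w) + α)` with
   `X ~ U(−1,1)` and `α = 10⁻⁸` keeping the step finite when fitness
   is flat.
5. Clip to bounds, re-evaluate, archive the elitist best and reinject
   it over the worst row.

Design notes, where the construction was genuinely open:

- `S` is fixed to the all-ones row (undefined in the source
  construction); this recovers the canonical sparrow scrounger step.
- The scrounger exponent keeps the printed `γ·i_max` denominator
  (canonical sparrow search uses the squared rank); the exponent is
  clamped at ±700 to keep arithmetic finite before clipping.
- The danger-group comparisons are stated in minimisation style in
  the source; fitness here is maximised, so they are
  orientation-adjusted.
- Elitism is added: without it the stochastic moves can lose the best
  solution, and the monotone best-trace invariant would not hold.
- `T2` is drawn once per iteration, `γ` fresh per update, both
  `U(0,1)`-type draws; draw order is fixed, so a seed fully
  determines the trace.
- A genetic-algorithm hyperparameter table (crossover/mutation/
  roulette selection) in the source material is inconsistent with the
  update equations above and is not implemented.

`random_search` with the identical evaluation budget
(`e·(i_max + 1)` objective calls) is the built-in baseline.

## Training protocol

Stratified split: `train_pct`% of each class to training (default
90), the rest to test; 10% of the training part per class is carved
out as the validation slice. The optimizer maximises
`(accuracy + sensitivity + specificity)/3` of the candidate weights
on that validation slice; the test part is untouched until final
metrics. Weights are searched in the box [−2, 2] — wide enough to
saturate the gates, narrow enough to keep the search effective — with
population 20 and 50 iterations as the desk-scale default.

The count-based fitness is discrete and saturates quickly on a small
validation slice, leaving the optimizer indifferent among many
perfect-on-validation solutions. Ties are therefore broken toward
lower validation cross-entropy: the objective subtracts
`10⁻⁴·min(loss, 10)`, which is far below the fitness quantum
(1/(3·n_val)), so the ordering is lexicographic — fitness first,
margin second. This favours larger-margin solutions, which
generalise better; the reported fitness is always the pure
three-metric mean.

Whether the metaheuristic should tune raw weights, initial weights or
only hyperparameters is stated inconsistently in the source material;
this package implements direct weight/bias optimisation, which is the
only reading under which the optimizer "substitutes" the
gradient-descent trainer.

The per-iteration trace records best/mean objective and the
validation cross-entropy of the best-so-far, supporting convergence
plots; "epochs" in that context are optimizer iterations, as no
gradient epochs exist.

## Synthetic EEG world

The generator emulates exactly two regimes:

- **interictal background**: Gaussian noise shaped to a `1/f` power
  spectrum (β = 1), RMS 20 µV — the standard surrogate for resting
  scalp EEG;
- **ictal segments**: a Hann-enveloped sinusoid at a frequency drawn
  from 3–8 Hz, random phase, peak amplitude `gain × 20 µV`, added to
  the background on every channel of the labelled window.

Defaults: 256 Hz, 2000-sample segments, 19.4% ictal (the focal/
non-focal balance of the public pediatric scalp-EEG corpus this
pipeline is shaped for), gain 3; the "strongly separable" test world
uses gain 5. Per-record seeds are `master_seed + index`.

What it does **not** emulate: physiological seizure morphology
(evolving frequency, spike-wave complexes), artifacts (EMG, eye
blinks, electrode pops), inter-channel structure, or non-stationary
background. A green end-to-end test therefore establishes that the
pipeline can recover a stated, learnable class structure — not
clinical performance. The published headline numbers on clinical
recordings (97.5%-range accuracy) require the external corpus and
full-scale training and are intentionally out of desk-scale reach.

## Numerical choices and degenerate inputs

- float64 everywhere; stable sigmoid/softmax (max-shift).
- Filter pad length scaled to the slow pole (above).
- Metrics computed with exact rational arithmetic on counts, then
  converted to float; undefined ratios (empty class) report 0, but
  the training fitness refuses single-class validation sets outright.
- ROC thresholds sweep unique scores; ties collapse to one point;
  AUC by trapezoid.
- EDF stores int16 against the ASCII-truncated physical range
  actually written to the header, so a read-back is exact to one
  digital step; files whose channels disagree on samples-per-record
  are rejected rather than resampled.
- Degenerate optimizer bounds (low = high) collapse the population to
  a point rather than erroring, matching the documented contract.

## Known limitations

- Optimizer-driven training scales poorly past a few thousand
  parameters; the full-scale (100 hidden units, 2000-step input)
  configuration is constructible but not trainable within test
  budgets.
- Channel handling is plain feature averaging; montage-aware
  spatial modelling is out of scope.
- The EDF codec covers plain continuous EDF only (no EDF+
  annotations, no discontinuous records).
- k-fold evaluation refits per fold with a reduced budget by default;
  its numbers are coarser than the train-percentage protocol's.
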