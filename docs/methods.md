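# Methods

## The problem

EEG hyperscanning records two interacting people simultaneously. The
scientific question behind this package is whether the *dyad type* — a
control pair of two neurotypical participants (TD–TD, label 0) versus a mixed
pair including one autistic participant (ASC–TD, label 1) — can be decoded
from one second of the two EEG streams. Labeled hyperscanning data is scarce,
so the pipeline is built around self-supervised pretraining: a large pool of
*unlabeled* single-brain resting EEG teaches an embedder what one second of
EEG "looks like", and only the final dyadic classifier needs labels.

## Temporal shuffling (the pretext task)

Continuous EEG is cut into 1-s epochs (inclusive-endpoint convention: 501
samples at 500 Hz; consecutive epochs share one boundary sample). From the
epoch sequence we draw triplets `(x_e, x_e', x_e'')` with two anchors
`e < e''` at most `tau_pos` epochs apart and a probe `e'`. The label is

    y = +1  if e < e' < e''   (ordered)
    y = -1  otherwise          (shuffled)

The embedder `h_theta : R^(C x T) -> R^D` maps each epoch to a D-vector; the
contrastive feature is the concatenation of elementwise absolute differences

    g_TS = ( |z_e - z_e'| , |z_e' - z_e''| )  in R^(2D)

and a linear head `(w, w0)` scores it. Embedder and head are trained jointly
on the mean logistic loss `mean log(1 + exp(-y (w.g + w0)))`; at `w = 0,
w0 = 0` this is exactly `ln 2` for any data, a value the tests pin down.

**Negative context.** Where the shuffled probe comes from is the one place
the task's published descriptions genuinely underdetermine the sampler, and
it decides whether the task is solvable. This implementation samples shuffled
probes from the *negative context*: epochs more than `tau_neg` (default 3)
away from the nearest anchor, following the source formulation of temporal
shuffling. The alternative reading — probes *within* `tau_neg` of an anchor —
is available as `negative_mode="near"`, but it caps attainable accuracy
severely: with anchors up to 10 epochs apart and near probes at most 3
outside, the joint distribution of the two time gaps overlaps between classes
(a probe 1 epoch before the anchors of a 2-epoch pair produces the same gap
pair (1, 3) as an interior probe of a 4-epoch pair), and a direct Bayes
enumeration over the sampler's discrete gap distribution bounds *any*
gap-based classifier at 76% — with a linear head on absolute differences,
at ~72% before noise. The far reading has no such collision and supports the
~90% regime the method is known for.

**One-epoch positive context.** With `tau_pos = 1` no epoch fits strictly
between the anchors, so the ordered class cannot be sampled at all. The
sampler does not silently repair this: it emits an all-shuffled set and
reports the class counts. A model trained on it collapses to the
majority class and scores exactly chance on a balanced reference task —
which is the mechanism by which short positive contexts fail (minority-class
starvation), not per-sample difficulty. For `tau_pos >= 2` the sampler
balances ordered/shuffled counts to within one by default
(`balance=False` gives Bernoulli(1/2) labels instead).

**Comparing context lengths.** Validation accuracy is not comparable across
`tau_pos` values because the task itself changes. `sweep_context` therefore
also scores every trained model on one shared reference triplet set sampled
at the largest requested context; that column is the comparable one.

## The embedder

A shallow convolutional network in the brain–computer-interface tradition:

1. temporal convolution, one bank of `F` kernels (length `k`) applied to
   every channel independently;
2. spatial aggregation: each output map is a learned linear combination over
   all channels and temporal filters (no bias — batch norm owns the offset);
3. batch normalization per feature map;
4. squaring, temporal average pooling, `log(max(., 1e-6))` — together an
   estimate of log band power of the learned filters;
5. dropout and a linear map to `D` dimensions.

At full scale (C=61, T=501, F=40, k=25, pooling 75/15, D=100) the embedder
has 206,820 trainable parameters; adding the 2D+1 = 201 parameters of the
pretext head gives the pretext model's total of 207,021. The
count is a closed-form function of the configuration and is asserted against
the built network.

The network, its backward passes, and the Adam optimizer are implemented in
NumPy (`dyadbrain._nn`). Gradients are analytic and verified against central
finite differences (full-gradient relative error ~1e-10 on a small model;
the acceptance bound is 1e-4). Evaluation-mode forward passes are
deterministic: dropout off, batch normalization on frozen running estimates.

**Optimizer defaults.** The embedder trains with Adam at lr 1e-4; the linear
pretext head, which starts at exactly zero, gets its own rate of 5e-2. Adam
moves each parameter by at most ~lr per step, so a head whose optimum lies
several units from the origin cannot be fit in a few hundred iterations at
the embedder's rate — with a shared small rate the head stays near zero and
validation accuracy sits at ~57% while a logistic regression fit to the same
frozen features reaches ~94%. Batch size 128, 200 iterations, early stopping
on validation loss with patience 10 evaluations (evaluated every 5
iterations), best-validation weights restored.

## The multi-brain classifier

Two embedder instances (copies of the pretrained weights, or freshly
initialized for the supervised baseline) embed the two simultaneous epochs of
a dyad; the embeddings are fused (concatenation by default; absolute
difference and sum are config options) and a fully connected head
(2D -> 100 -> 50 -> 1, rectified-linear, dropout 0.38, sigmoid output)
predicts P(ASC–TD). Training minimizes binary cross-entropy with Adam
(default lr 9.3e-4). The two embedders are fine-tuned by default;
`tie_embedders` makes them share parameters and `freeze_embedders` fixes
them — the upstream protocol does not pin these down, so they are switches.

**Splits and leakage.** `split="epoch"` (the study protocol) partitions
epoch pairs 90/10 train/eval and the eval part 90/10 validation/test;
epochs of one dyad can appear on both sides. On synthetic data this is
catastrophic in a specific, instructive way: each generated dyad has a
stationary spectral fingerprint (fixed phases, per-channel drift loadings),
so a flexible model can memorize dyad identity and read the label off it —
a no-effect dataset evaluates at 100% under epoch-level splits.
`split="dyad"` holds out whole dyads (80/10/10 by dyad) and is the mode the
learning experiments and the acceptance checks use; the null check
additionally evaluates on dyads generated independently of training.

**Evaluation.** Confusion counts treat the mixed dyad as the positive class.
Precision, recall, specificity, F1 and accuracy come from the counts, with
undefined ratios reported as NaN and flagged rather than coerced to 0.
ROC AUC is computed on raw probabilities (verified in tests against the
O(n²) pairwise-concordance statistic). Accuracy is additionally reported as
the mean over consecutive groups of 5 test pairs in a once-shuffled seeded
order, matching the batch-of-five evaluation convention.

## The spectral-biomarker baseline

Per participant: Welch PSD per epoch and channel (one Hann window spanning
the 1-s epoch, ~1 Hz resolution); five bands — delta [2,4), theta [4,8),
alpha [8,12), beta [12,30), gamma [30,48] — in absolute (band-average PSD)
and normalized form. The normalized marker is the band's share of integrated
broadband power over 2–48 Hz, so the five normalized markers sum to exactly 1
(the published description divides "absolute by total", which with
band-averages and unequal band widths cannot sum to one; the integral form
preserves the partition property and is what "relative power" means in
practice). Each of the 10 markers' (epoch x channel) table collapses to four
descriptors — mean of channel means, mean of channel stds, std of channel
means, std of channel stds, with the inner statistic over epochs (population
std, divisor n; the alternate inner-over-channels order is a config switch) —
for 40 features per participant, concatenated to 80 per dyad. A
standardized L2 logistic regression with seeded cross-validated grid search
over the regularization strength classifies the dyads.

## Synthetic data

The generator produces the statistical structure the method assumes, not
biophysically realistic EEG:

* each channel is a sum of sinusoidal oscillations (defaults 3, 6, 10, 16,
  25 Hz; base amplitude 1.5) over 1/f-shaped Gaussian noise (std 0.5,
  spectral exponent 1, both configurable);
* every (channel, oscillation) amplitude drifts under an independent
  Ornstein–Uhlenbeck process with stationary relative std 0.6 and timescale
  20 s. Independence across channels and rhythms matters: the temporal-
  shuffling decision needs many independent slowly-drifting spectral
  coordinates for the embedding-distance noise to average out. The timescale
  must exceed the largest triplet span (tau_pos + tau_neg = 13 s), otherwise
  the spectral state decorrelates inside the positive context and temporal
  order becomes unreadable at the context edges;
* dyads share their oscillators' phase structure: member 2's phases are
  member 1's plus `(1 - coupling) * eta`, `eta ~ U(-pi, pi)` per channel and
  oscillation, so phase-locking grows monotonically with `coupling` in
  [0, 1]. Group effects: a mixed dyad multiplies member 1's alpha-band
  amplitude by `alpha_power_ratio` (default 1.5; the learning experiments
  use 2.0) and defaults to weaker coupling (0.1 vs 0.3), echoing reported
  alpha-power alterations and reduced inter-brain synchrony. Setting the
  ratio to 1 and equalizing coupling yields the null condition, under which
  the dyadic biomarker distribution is label-independent (checked by
  two-sample tests).

Every generator is a pure function of its config including the seed.

What passing tests on this data do **not** show: robustness to artifacts,
volume conduction, inter-subject variability, non-sinusoidal rhythms, or any
property of real clinical recordings. The synthetic dyad-type effect is a
stipulation, not an estimate of the real effect size.

## Problem sizes

The architecture defaults target the full recording regime (61 channels at
500 Hz). The learning experiments run at a reduced scale chosen as this
package's standard study condition: 8 channels at 100 Hz (T=101), a smaller
embedder (16 temporal filters, kernel 25, pooling 25/5, D=50), 12 recordings
of 120 s for pretraining (150 triplets each), 10 dyads per class of 60 s for
the downstream task, and 2x8 + 2x8 null dyads of 40 s. Full-scale
construction and parameter counting are exercised directly; nothing about
the reduced regime changes the algorithms.

## Numerical choices

* FIR filtering is zero-phase Hamming-window `firwin` design (notch width
  2 Hz, transition bands per mne's defaults, 25%-of-cutoff capped); filters
  commute with time reversal to ~1e-12.
* Bad channels are rebuilt by spherical-spline interpolation on the head
  sphere (via mne); a constant field is reproduced to ~1e-12 relative.
* Ocular cleanup is a deterministic regression projector: channels whose
  absolute correlation with the EOG trace (or a frontal bipolar proxy)
  exceeds 0.8 have the least-squares EOG component subtracted. This is a
  simple, reproducible stand-in for ICA-based classification and makes no
  claim of equivalence to component-label semantics.
* Epoch rejection is a global peak-to-peak threshold; `"auto"` picks it
  from quantile candidates (0.6–1.0) of the per-epoch ptp distribution by
  5-fold cross-validated reconstruction error (mean of surviving training
  epochs vs median of held-out epochs), ties to the smaller threshold.
  Per-sensor thresholds and repair are out of scope.
* The log non-linearity is floored at 1e-6; all-zero inputs embed to finite
  vectors.
* EDF files are 16-bit with per-channel physical ranges re-parsed from their
  8-character header encodings before digitization, so a round trip through
  any conforming reader errs by at most one quantization step. Recordings
  are zero-padded to whole 1-s records; `bads` and sensor positions are not
  representable in EDF and are dropped on write.

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; full-scale
  pretraining (61x501, batch 128) is possible but slow — the package is
  sized for method verification, not cluster-scale pretraining.
* Null-condition accuracy on held-out dyads is a per-dyad Bernoulli average;
  with few evaluation dyads its variance is dominated by dyad count, which
  is why the null check evaluates on 16 independent dyads.
* The hyperparameter search utility is a seeded random search, not
  tree-structured Parzen estimation; relative-positioning and predictive-
  coding pretext variants are not implemented.
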