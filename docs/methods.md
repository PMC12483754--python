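# Methods

## Problem setting

`eeglrp` implements an explainable diagnostic analysis for two-class
resting-state EEG: a shallow convolutional classifier separates patients
from controls, layer-wise relevance propagation (LRP) attributes each
decision to channels and time points, and the attribution drives an
automatic channel-selection procedure whose cost/performance trade-off is
mapped on a channel-count × data-length grid. Group-level differences in
attribution are tested per channel with FDR control. Because clinical EEG
of this kind is not openly distributable, the package ships a synthetic
cohort generator so that the entire analysis is exercisable and testable
end to end.

## Preprocessing

The conditioning chain for raw recordings is fixed: zero-phase 4th-order
Butterworth bandpass (default 1–55 Hz), polyphase anti-aliased resampling
(default to 200 Hz), common average reference (CAR), cropping to a common
length (default 180 s), and non-overlapping segmentation from the start of
the recording (remainder discarded; half-open sample windows, 0-based).
Zero-phase filtering is used so that filter latency cannot displace
relevance in time. An artifact-removal stage (ICA in clinical practice) is
present as an explicit no-op: the pipeline assumes artifact-free input and
the generator produces none.

## Classifier

The model follows the FBCSP-inspired shallow ConvNet family: a temporal
convolution shared across channels, a spatial convolution collapsing the
channel axis, ReLU, mean pooling over time, dropout, and a dense softmax
readout. Default dimensions are the reference ones at 200 Hz — 40 temporal
filters of 25 samples (0.125 s), 40 spatial filters, pooling 75/stride 15.
A square/log activation variant is available behind a flag for training.

Training is mini-batch Adam on the cross-entropy with the study's
hyperparameters as defaults: learning rate 0.001, dropout 0.5, batch size
2, 200 epochs. Inputs are z-scored per channel with statistics estimated
on the training set only (no leakage). After every epoch the validation
set is scored; the parameter snapshot with the highest validation accuracy
is retained (ties: lower validation loss, then the earlier epoch).

Evaluation is subject-wise leave-one-out cross-validation: each subject is
the test case exactly once and the N−1 remainder is split 4:1 into
training and validation, stratified by class and seeded per test subject
(so results are invariant to cohort ordering). One training example is one
segment of the configured length; a subject's prediction averages the
softmax probabilities of its segments and takes the argmax. Sensitivity is
recall on the patient class, specificity on the control class.

The network and its training loop are implemented directly on NumPy
arrays with explicit forward and backward passes (verified against
numerical differentiation in the test suite). This keeps every
intermediate activation addressable for relevance propagation. Training
runs in float32; attribution runs in float64.

## Relevance propagation

The predicted class's pre-softmax score is decomposed by the
epsilon-stabilised proportional rule, with the stabiliser scaled per layer
to ε·mean|z| (ε = 10⁻⁶ by default). ReLU and dropout are pass-throughs.
Mean pooling is treated as a linear layer with weights 1/L and propagated
with the same epsilon rule, i.e. each window member receives relevance in
proportion to its activation. The alternative of splitting pool relevance
equally across the window was evaluated and rejected: it routes relevance
through ReLU-silenced units whose pre-activations are near zero or
negative, and the following epsilon step then divides by those tiny
denominators, which in practice buries the informative channels in noise
(planted-channel recovery on synthetic cohorts drops from 4–5/5 to ~2/5).

Bias terms absorb their proportional share of relevance. That share is
recorded per layer as a "leak", and conservation is audited in leak-aware
form: at every layer, the relevance total plus the leak absorbed above it
must equal the propagated score. With this accounting the audit is exact
to floating-point precision; the raw input-relevance total alone is *not*
close to the score once trained biases are sizeable, which is inherent to
bias-absorbing epsilon LRP rather than an implementation artefact.
Relevance stays signed end to end; absolute values are taken only where a
consumer explicitly requires them. A zero output score yields an all-zero
map by definition.

## Channel selection

Per leave-one-out fold: relevance maps are computed for each validation
subject with the fold's full-montage model, averaged over time points into
a channels × n\_validation matrix, averaged within each class, rectified
(absolute value) and L1-normalised into a channels × 2 matrix. Each
channel's score is the maximum over the two class columns; channels are
sorted by descending score (ties broken by montage order) and the top k
are selected. A fresh model is then trained on the k-channel data of the
same train/validation split and evaluated on the fold's test subject. The
test subject's data never enters the ranking. L1 was chosen for the
normalisation step (the field uses several conventions); the signed,
non-rectified variant is available behind a flag.

## Statistics

Between-cell accuracy comparisons on the evaluation grid use independent
two-sample t-tests on per-subject 0/1 correctness vectors (the replicate
unit had to be chosen; subjects are the natural exchangeable unit), with
Benjamini–Hochberg correction across all cell pairs; pairs with q > 0.05
are flagged as not significantly different. Group comparisons of
attribution first L1-normalise each subject's absolute channel-relevance
vector (so every subject contributes unit mass), then run per-channel
independent t-tests, patient vs control; raw p-values drive significance
calls at α = 0.05, with BH-adjusted q-values exported alongside.

## Synthetic cohorts

Each subject's signal is a sum, per channel, of

* pink (1/f^β) background noise synthesised in the frequency domain
  (β = 1, 8 µV RMS by default);
* band-limited Gaussian oscillations — white noise bandpassed to delta
  (1–4 Hz, 4 µV), theta (4–8 Hz, 4 µV), alpha (8–13 Hz, 8 µV; dominant, as
  in eyes-closed rest) and beta (13–30 Hz, 2 µV);
* white sensor noise (1 µV RMS).

A lognormal per-subject gain (σ = 0.2) on each band's amplitude models
between-subject variability. Class effects multiply a band's amplitude on
named channels of patient subjects only (the default demonstration effect
triples alpha at FCz, CPz, Oz, O1, O2). The output dialect is "already
preprocessed": band-limited to 1–55 Hz (capped below Nyquist) and
common-average-referenced; a broadband flag emits unfiltered wide-band
data (e.g. at 1000 Hz) to exercise the conditioning chain. Subjects are
drawn from independent streams seeded by (cohort seed, class, index), so
any subject and any cohort are exactly reproducible.

What the generator does **not** model: volume conduction (channels are
independent up to the shared reference), artifacts (blinks, ECG, EMG),
non-stationarity, and any claim about the true effect sizes of clinical
populations — the planted effect is a detectability dial for validating
the machinery, not a statement about pathophysiology. Passing tests on
these cohorts demonstrate that the pipeline recovers what was planted
under its stated assumptions; they do not certify performance on clinical
recordings.

## Problem sizes used in tests and the acceptance script

The shipped evaluations run on one CPU in the NumPy implementation, so
they use scaled-down study conditions, chosen once: cohorts of 16+16
(test suite) or 10+10 (acceptance script) subjects, 60 s per subject
generated directly at 64 Hz and cut into two 30-s segments, alpha tripled
at the five planted channels, and a reduced network (4 temporal / 4
spatial filters, kernel 13, global mean pooling) trained for 50 epochs
with the default batch size 2 and learning rate 0.001. 64 Hz keeps the
full 1–30 Hz oscillation range below Nyquist while making 62-channel
training affordable; two segments per subject matter because the readout
margin grows with the number of optimisation steps, and single-segment
cohorts leave the k-channel retrained models under-trained at this
learning rate (their decisions hover near the softmax midpoint). Controls
(label shuffles, null cohorts) run at 6–8 subjects per class on an
8-channel montage at 100 Hz.

Global mean pooling deserves a note: with one 30-s segment per subject, a
cohort of ~25 training examples cannot support the default pooled feature
map (hundreds of features) — the dense layer then memorises training
subjects (training accuracy 100%, validation at or below chance). A single
pooling window spanning the post-convolution length reduces the readout to
one feature per spatial filter, which is exactly the rectified band-power
statistic the task calls for; resting-state signals are stationary, so
nothing is lost by pooling over the whole segment. At the full reference
geometry (dozens of subjects × six 30-s segments at 200 Hz) the default
75/15 pooling is appropriate.

## Numerical choices and degenerate inputs

* Filters: SOS biquad cascades, forward–backward (`sosfiltfilt`).
* Resampling: `resample_poly` with the rational ratio of target to source
  rate; output truncated to ⌊n·target/source⌋ samples.
* t-tests: equal-variance two-sample; two identical samples return
  t = 0, p = 1; zero pooled variance with unequal means is an error.
* EDF: 16-bit encoding against the per-channel physical range; constant
  channels are widened to ±1 to avoid a degenerate scale. Round-trips are
  exact up to quantization (verified against MNE's independent reader).
* Ranking ties break by montage index; stable sorts throughout.
* All stochastic components (generator, parameter init, splits, batch
  order, dropout) derive from explicit seeds; per-subject fold seeds hash
  the subject id so LOOCV is order-invariant.

## Known limitations

* LRP is implemented for the ReLU variant; the square/log variant trains
  but has no defined propagation rule here.
* The epsilon rule is the only variant (no αβ, no z⁺); gradient×input and
  occlusion baselines are out of scope.
* The between-cell t-test on correctness indicators is a pragmatic choice;
  correctness vectors are binary and heteroscedastic, so borderline
  q-values should be read cautiously.
* CAR spreads a weak copy of any localized effect into all channels
  (zero-sum across the montage); on real data with correlated sources this
  is negligible, on synthetic independent channels it is visible if the
  generator skips its own referencing step.
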