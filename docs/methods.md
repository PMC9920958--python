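# Methods

## Problem and pipeline

The package classifies human activities — five fall styles plus seven
daily activities (walking, standing, sitting, picking up an object,
jumping, lying down, and an unknown class) — from sequences of 2-D
skeletons. Each frame contributes 17 COCO-order joints as `(x, y, score)`
triples (51 attributes). A sliding window of 36 consecutive frames
(2 s at 18 fps) is summarized by its first, middle, and last frame,
concatenated to a 153-float vector; windows step by one frame by default.
Window labels use majority vote over per-frame labels with the last
frame's label breaking ties (the labeling rule is configurable).

## Numeric tokenization

All 153 features share one global scale: `F_min` and `F_max` are the
scalar minimum and maximum over every cell of the fitted table, and

```
id = floor( V · (F − F_min) / (F_max − F_min) ),   V = 30,000
```

keeping the integer part, so ids span 0…30,000 inclusive. Values outside
the fitted range clamp to the boundary first; this matters when the scaler
is fitted on the training split only (`fit_scope="train"`, the default,
which avoids leakage — `fit_scope="all"` reproduces fitting on the entire
dataset). Three special ids live above the numeric range in a from-scratch
embedding table: `[PAD] = 30,001`, `[CLS] = 30,002`, `[SEP] = 30,003`
(vocabulary 30,004). A window encodes to `[CLS]` + 153 ids + `[SEP]` = 155
tokens with an all-ones attention mask; at this fixed length no padding is
ever needed. Special-token framing can be disabled, but `[CLS]` pooling
requires it, so it defaults on.

Design notes: the mapping is deliberately *global* (one scale for every
feature), not per-feature; the quantization resolution is
`(F_max − F_min)/30,000`, so any two values more than one bin apart get
distinct ids, and the mapping is monotone by construction.

## Classifier

A BERT-style encoder: token embedding plus learned positional embedding
(layer-normalized, dropout 0.1), `L` post-layer-norm transformer blocks
(multi-head self-attention, GELU feed-forward), then the final-layer
embedding at the `[CLS]` position through dropout 0.1 and a linear map to
12 logits. The default configuration is the standard base stack
(12 layers, 768 hidden, 12 heads, 3072 feed-forward); a `tiny` preset
(2 layers, 64 hidden, 4 heads, 128 feed-forward) exists so the full
pipeline runs in minutes on one CPU core. The networks run on the
package's own numpy reverse-mode autograd (`skelseq.nn`); every operator's
gradient is checked against central finite differences in the test suite.

Training: cross-entropy, AdamW (decoupled weight decay 0.01; biases and
layer-norm parameters exempt), batch size 16, up to 20 epochs, the best
epoch chosen by validation macro-F1. The reference learning rate 2e-5 is
a *fine-tuning* rate and presumes pretrained weights; training the
from-scratch encoder at desk scale needs a larger rate, and the
experiments here use 1e-3 (chosen once from the overfitting behavior on a
small separable corpus, before any comparative runs). Splits are
70/15/15, stratified per class by deterministic largest-remainder
allocation (classes with fewer than 3 windows stay whole in the training
split); a `grouped_by_source` mode keeps whole recordings in one partition
because unit-stride windows overlap and leak across random splits. Class
weighting in the loss exists behind a flag but defaults off: rebalancing
is the augmentation module's job.

## Conditional tabular GAN

Continuous columns are encoded by mode-specific normalization: a
variational Gaussian mixture (scikit-learn `BayesianGaussianMixture`,
up to k = 10 components, weight prior 1/k) is fitted per column,
components below weight 1e-3 are pruned, and components closer than
1.5 pooled standard deviations are merged weight-proportionally — a
single Gaussian split by the variational fit across overlapping
components collapses back to one component with nearly the population
moments, while separated modes survive. A value becomes
`alpha = (x − mu_mode)/(4 sigma_mode)` (clipped to [−1, 1]) plus a one-hot
mode indicator, the mode drawn from the posterior responsibilities;
decoding inverts exactly whenever alpha is unclipped. Column fits
subsample to at most 1,500 rows for speed.

Generator and discriminator are two-hidden-layer MLPs (256, 256; ReLU and
leaky-ReLU respectively). The generator receives 128 Gaussian noise
dimensions plus the 12-slot conditional one-hot and outputs, per column,
a tanh alpha and mode logits (Gumbel-softmax, temperature 0.2), plus class
logits; the discriminator sees the encoded row concatenated with the
conditional vector. Losses: non-saturating BCE for both nets; the
generator additionally pays (a) a cross-entropy penalty forcing its class
logits to match the condition (weight 1) and (b) a condition-wise moment-
matching penalty (weight 5) pulling the generated batch's per-class mean
and variance in encoded space toward the real batch's. The moment term
is what makes small-data adversarial training stable enough to recover
per-class means reliably; with it, 300 epochs at batch 64 recover the
class means of a two-class Gaussian toy to well within half a standard
deviation across seeds. Adam-style updates use betas (0.5, 0.9) at
learning rate 2e-4 without weight decay.

A numerical caveat at full window dimensionality (153 columns ≈ 1,100
encoded dimensions): a BCE discriminator can separate generated rows from
real ones through the soft-vs-hard one-hot artifact of Gumbel-softmax
outputs, and its gradient then collapses the generator's conditioning
(every condition produces the same majority-like row). The method this
encoder follows counters that with a Wasserstein critic and gradient
penalty, which needs second-order gradients the numpy core does not
provide. The package therefore exposes `adversarial_weight` (and optional
instance noise on discriminator inputs); the end-to-end experiments run
the generator on the moment-matching and conditional losses alone
(`adversarial_weight=0`), which produces minority-class rows that a
nearest-centroid probe assigns to the correct class 100% of the time,
while low-dimensional problems keep the full adversarial game (default
weight 1).

Training-by-sampling draws the conditioning class from the empirical
class frequencies, and the real rows shown to the discriminator are drawn
from the conditioned class. With raw frequencies a < 1% minority class
appears in almost no batches, so the generator never learns it; the
log-frequency option (`log_frequency=True`, probabilities ∝ log(1+n_c))
gives minority classes usable sampling mass and is what the end-to-end
experiments use. Sampled rows are decoded back to feature scale; the
class label of a generated row is the requested condition by construction.

Augmentation planning: the `table3` strategy reproduces the published
per-class synthetic counts (17,267 / 6,731 / 7,533 / 16,759 / 7,747 /
14,784 / 13,244 for the seven augmented minority rows — about 40% dataset
growth; the distribution table's row order disagrees with the activity
list, so these counts are keyed by row position). The `target_share`
strategy raises every class below a requested share of the final total up
to exactly that share (default 1/12, i.e. parity). Synthetic rows are
appended to the training split only and tagged by provenance; validation
and test stay purely real.

## Evaluation

The confusion matrix (rows = true, columns = predicted) is collapsed
one-vs-rest per class: accuracy (TP+TN)/N, precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP), F1 = 2PR/(P+R), reported in percent
with 2-decimal rendering, plus support. Per-class accuracy is
deliberately the one-vs-rest accuracy (twelve distinct values). Ratios
with zero denominators are reported as 0 and flagged rather than NaN, so
the macro row — the *unweighted* mean over classes — is always defined.
Run comparison checks both arms scored a bit-identical test split (hashes
in the run manifests) and reports macro deltas plus per-class recall
deltas.

## Synthetic motion generator

The generator emulates labeled 17-joint trajectories, not biomechanics:
a canonical standing template is placed at a class-specific horizontal
anchor and animated analytically — periodic limb oscillation for walking
and jumping, small sway for standing, squashed postures for sitting and
lying, a down-and-up dip for picking up an object, and, for the five fall
classes, a monotone downward displacement of the upper body (110–170 px
over 0.8–1.2 s, with class-specific horizontal lean) starting mid-
sequence. Gaussian pixel noise (default SD 3 px, roughly pose-estimator
jitter) is added and coordinates are clipped to a 640×480 frame; joint
scores are uniform on [0.5, 1] so the score channel is informative but
carries no class signal. Sequences default to 4 s (72 frames → 37
unit-stride windows). The `upfall_like` imbalance profile allocates a
window budget proportional to the published per-class window counts
(walking 18.59%, each fall class under 1%) by largest-remainder rounding.

Because the archetypes are analytic, classes are linearly separable in
window-feature space as noise → 0 (a nearest-centroid classifier reaches
100%), which the tests verify. Consequences for interpretation: passing
tests show the *pipeline machinery* — tokenization, training, splitting,
augmentation bookkeeping, metric computation, and the direction of the
imbalance→augmentation effect — behaves correctly; they do not certify
accuracy on real video, where pose errors are non-Gaussian, classes
overlap, and within-class variation is far richer.

## Desk-scale study sizes

The comparative experiment (plain vs GAN-augmented training) runs at desk
scale on one CPU core: a 4,000-window corpus with the `upfall_like`
profile (each minority class ≈ 28 windows), pose noise 15 px (the regime
where minority classes are genuinely hard to learn from their few real
windows while majority classes stay learnable), the tiny encoder preset,
8 training epochs at learning rate 1e-3, generator training for 120
epochs at batch 64 with log-frequency condition sampling, and minority
classes raised to a 5% share of the final training total — the published
augmentation intensity (about 40% dataset growth). With 4–6 test windows
per minority class, per-class recall is quantized in steps of 17–25
points, so the comparison is directional, not a precise effect-size
estimate; single boundary flips move individual class recalls by large
amounts. Both arms share the
corpus, split, scaler, and test windows bit-for-bit; only augmentation
differs. All stage seeds derive from one global seed by hashing, so any
stage can be rerun in isolation.

## Known limitations

- The from-scratch encoder at desk scale is not the 110M-parameter
  pretrained model; headline accuracies on the real corpus are out of
  reach by design, and the comparison is directional.
- The GAN generates at the window-feature level (as in the protocol it
  follows), not raw keypoint time series; temporal consistency across
  overlapping windows is not modeled.
- Multi-person frames are reduced to the highest-mean-score detection;
  there is no cross-frame identity tracking.
- Mode merging at 1.5 pooled SDs can fuse genuinely close-but-distinct
  modes; k and the merge threshold are configurable where that matters.
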