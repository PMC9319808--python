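# Methods

This package is a controlled validation study of two explanation
methods — automated concept-based explanation (ACE) scored with concept
activation vectors (TCAV), and (Guided) Grad-CAM — as bias-discovery
tools for histopathology-style image classifiers.  Because real
whole-slide images cannot ship with the code, the study runs end to end
on synthetic tiles whose statistical structure mimics the relevant
properties of H&E-stained skin tissue, with biases planted by
construction so that ground truth is available for every check.

## Synthetic tiles

A tile is a `T×T×3` uint8 image (default `T = 96`; `T = 256` is the
full-fidelity setting) composed of:

* **stroma** — a pink base colour with smooth low-frequency
  multiplicative texture and pixel noise;
* **nuclei** — dark purple ellipses at Poisson-random positions.  The
  positive ("cancerous") class draws more and larger nuclei
  (rate 20 vs 14 per 96 px tile, mean radius 4.2 vs 3.6 px); this
  density/size contrast is the *only* legitimate class signal;
* **collagen** (optional stratum) — wavy fibre bands standing in for
  reticular dermis, present in half of negative and 15% of positive
  tiles;
* **background** (optional stratum) — near-white glass; a tile may
  carry at most a small pocket of it, because tiles with more than 10%
  near-white pixels (all channels ≥ 240) are rejected and regenerated,
  mirroring the white-area filter used when tiling real slides.

Tiles are grouped into virtual slides.  Each slide carries a
deterministic stain-colour jitter (±8 per channel) and a lognormal
nucleus-density factor (σ = 0.35).  The slide effects are the crux of
the design: they make per-tile classification genuinely hard (a model
must generalise across slide appearance, not memorise it), which
reproduces the regime reported for the real-data experiments — an
unbiased model lands in the mid-range (AUC roughly 0.8–0.9), while any
planted shortcut lets the model saturate.  With the original, more
separated defaults the classifier simply ignored planted shortcuts, so
the separability was set once from the reported unbiased operating
range and then frozen.

Two **source regimes** emulate different scanner/stain settings: source
B tiles pass through a fixed per-channel affine map (+12% brightness, a
30% contraction of each channel toward a reference stroma colour —
brighter, less colour variation).  Splits are slide-disjoint at
66.67 / 16.67 / 16.67%.

What the generator does **not** emulate: real nuclear morphology,
chromatin texture, tissue architecture (glands, epidermis layering),
stain deconvolution physics, or scanner optics.  Passing tests
therefore show that the explanation pipeline recovers *planted,
ground-truthed* biases in a controlled setting; they do not certify
performance on real slides.

## Planted biases

* `class_ratio` — positive tiles enter the training pool with
  probability 0.5 (rejection sampling), giving ≈ 2:1 imbalance;
  validation/test untouched.
* `measurement` — slides are class-pure and the source regime follows
  the label exactly, in every split; no appearance normalisation is
  applied.  The label is perfectly predictable from global appearance.
* `sampling` — training tiles of the negative class exclude the
  collagen stratum; validation/test retain it.
* `class_correlated` — a flat red square (side `T/12`, offset
  `(T/24, T/24)`, colour (255, 0, 0)) is drawn on every positive tile in
  every split.

With `kind='none'` the label is independent of source and marker by
construction (verified by a chi-square property test on the tile plan).

## Classifier

A small ResNet-style CNN: 7×7/32 stride-2 stem → 3×3 max pool stride
2 → two residual blocks (3×3×32) → three residual blocks (3×3×64,
first at stride 2, 1×1 projection shortcut) → global max pool → 16-d
fully connected → 2-way softmax, Swish at every activation site.  At
256 px input the stem yields 128×128, stage 2 sees 64×64 and stage 3
outputs 32×32 maps; the body is fully convolutional, so the parameter
count is input-size invariant.

Training: Adam, learning rate 2·10⁻⁴, batch 32, L2 penalty 10⁻⁴ (the
coefficient is not fixed by the protocol; 10⁻⁴ is a standard magnitude,
config-exposed), inputs scaled to [0, 1], per-epoch shuffling,
inverse-frequency class weights, checkpoint on best validation loss,
early stopping with patience 50.  Augmentation: horizontal flip
(p = 0.5), rotation by a uniform angle in [0°, 360°), optional HSV
jitter (hue ±0.05, saturation/value ±20%; used in the two-source
feature-visualisation setting), and random cutout (one rectangle,
p = 0.5, side 10–40% of the tile, filled with grey 127).  The cutout
fill is load-bearing: concept patches are rendered on grey-127
canvases, and a network never trained on grey regions misreads them.
The class-ratio experiment uses its own protocol — a fixed epoch
budget with early stopping and class weights disabled — because class
weighting or long training lets the model absorb the imbalance.

The network and its backpropagation (including the guided variant) are
implemented directly on numpy: convolution via im2col + GEMM, max
pooling with argmax routing, analytic Swish derivatives, Adam.  All
gradients are finite-difference-tested.

Two additions are runtime devices, not protocol changes: an optional
validation-loss floor (5·10⁻³) ends training early once a shortcut cue
has saturated the model, and the stem convolution skips its (unused)
input gradient during fitting.

## ACE

Concept candidates come from SLIC-zero superpixels at three segment
counts (15/50/80 per tile).  The counts are tile-size independent:
because every generator feature scales linearly with the tile side,
fixed counts preserve the relative geometry of segments and image
content at any tile size (an area-proportional rule was tried and
discarded — it makes fine segments ~12× larger than the marker at 96 px
and the marker concept becomes unrecoverable).  Segments smaller than
0.5% of the tile are dropped.  Each surviving segment is placed on a
grey-127 canvas at its original location and scale — no resizing, since
cell size is a meaningful feature — and embedded at the 16-d FC layer.
Convolutional feature maps are deliberately not used for embedding:
they are not spatially invariant, and clustering on them groups patches
by location rather than appearance (kept as a regression test).
Embeddings are clustered with k-means (k-means++, fixed seed); k
defaults to 5 and is config-set per experiment, since too large a k
produces duplicate concepts and too small a k produces mixed ones.
Clusters with fewer than 20 members or drawing from fewer than 5
distinct tiles are discarded (thresholds config-exposed; reduced
proportionally at reduced problem sizes), and each concept keeps its 40
members closest (l2) to the center, ties broken by patch index.

## TCAV

For concept C, layer l (the FC-16 activation) and class k: a linear
SVM (hinge loss, L2, C = 0.1) separates concept embeddings from random
counterexamples — segments drawn uniformly without replacement from
the pooled SLIC segments, freshly per run.  The CAV v is the unit
normal oriented to the concept side.  The sensitivity of input x is
⟨∇h(x), v⟩ and

    TCAVQ = |{x ∈ X_k : S(x) > 0}| / |X_k|  ∈ [0, 1].

**Gradient target.**  ∇h is the gradient of the *log-odds* of class k
(logit_k − logit_other) with respect to the FC activation.  In a
two-class softmax only the logit difference moves the prediction; the
common component of the two logits is meaningless, and using a single
logit makes the score noisy precisely for the concepts that matter
(the marker concept's embeddings lower both logits while raising their
difference).  The log-odds target also makes class complementarity
exact: negating the gradient maps a score s to 1 − s.

Because the FC-16 layer is one linear map away from the logits, the
log-odds gradient is a *constant vector* across inputs; each run's
TCAVQ is therefore exactly 0 or 1, and the reported mean ± std over
runs is a Bernoulli mean (this is why saturated concepts print
1.0 ± 0.0 and borderline ones print values like 0.9 ± 0.31).

**SVM regularization.**  Random counterexample draws are contaminated
with concept-like segments at a few percent; with C = 1.0 about 2% of
runs flipped the CAV orientation (train accuracy dips flag exactly the
contaminated draws), while C = 0.1 anchors the direction to the bulk
separation (0 flips in 120 draws).

**Significance.**  Per run, a null score is computed from a
random-vs-random CAV on the same evaluation tiles; a two-sided Welch
t-test compares concept scores with null scores, significant at
α = 0.01, no multiple-testing correction across concept × class pairs.
The default is 20 runs (100 at paper scale): with binary per-run
scores, 10 runs cannot reach α = 0.01 even for a perfect concept
(t = 3.16, p ≈ 0.0115 against a fair-coin null), so 20 is the minimum
honest desk setting.  Evaluation inputs X_k are the test split's
class-k tiles, capped at 100.

## Saliency

Grad-CAM: weights α_k = spatial mean of ∂y_c/∂A^k over the last
stage-3 feature map (the deepest spatial layer), coarse map
ReLU(Σ_k α_k A^k), with y_c the pre-softmax logit.  Guided
backpropagation zeroes the backward signal at every activation site
where the incoming gradient or the forward pre-activation is negative;
the network uses Swish, so the gate uses the pre-activation sign and
the signal is additionally scaled by the Swish derivative.  Guided
Grad-CAM is the pointwise product of the bilinearly upsampled coarse
map with the guided-backprop image; quantitative checks use the
non-negative magnitude map (upsampled coarse × |gbp| summed over
channels).

## Bias flags

Operational proxies for what a human reads off the explanation
artifacts, thresholds config-exposed:

* **dominance shift** — each significant concept is assigned to the
  class where its mean TCAVQ is larger (provided it exceeds 0.5; exact
  ties count for neither); the flag fires when the negative,
  absence-defined class holds the majority.  Fractions over significant
  concepts sum to ≤ 1.
* **marker concept** — a significant positive-class concept whose
  patches intersect the marker region in ≥ 90% of cases.
* **source purity** — a significant concept with all patches from one
  source regime.

The biased/unbiased comparisons are *paired*: the unbiased control
shares the tile plan (minus the bias), the weight initialisation and
the training randomness, so only the planted bias varies.

## Problem sizes

* **desk** (default; used by `scripts/acceptance.py`): 96 px tiles,
  30 slides × 40 tiles, epoch budget 40 (30 for the class-ratio
  protocol), 20 TCAV runs, k = 5, ≤ 100 evaluation tiles per class.
* **replication scale** (seed sweeps in `analysis/03` and the test
  suite): 80 px, 16 slides × 16 tiles, 30 epochs, 20 runs.
* **mini** (fast checks): 64 px, 12 slides × 14 tiles.
* **paper**: 256 px tiles, 100-epoch budget, 100 runs — the
  full-fidelity setting, available behind config.

The shortcut experiments are insensitive to scale (the cue is exact);
the distribution experiments (class-ratio direction, sampling shift)
are direction-only claims checked across 5 seeds, as their magnitudes
depend on split composition at small test sizes.

## Numerical choices and degenerate inputs

float32 throughout the network (float64 in gradient tests); sigmoid via
tanh for overflow safety; ROC AUC by trapezoidal integration over
distinct score thresholds; zero sensitivities count as non-positive in
TCAVQ; a Welch test between two zero-variance equal samples reports
p = 1 (not significant); k-means refuses k larger than the sample;
constant images segment to a single flagged superpixel; empty cluster
filters warn and return no concepts; marker injection validates bounds
and is the identity for size 0.

## Known limitations

* The synthetic tiles are far simpler than real histology; results
  transfer as a statement about the *methods*, not about any tissue
  classifier.
* The FC-16 bottleneck makes per-run TCAVQ binary; std over runs
  therefore measures CAV-orientation stability, not per-input spread.
* k for k-means is user-set; no automatic model selection.
* Direction-only claims (class-ratio degradation, dominance shift) are
  majority-vote properties over seeds, with small test splits.
* The dominance-shift signature in particular depends on a concept-count
  asymmetry of real tissue — few distinct "cancer" concepts against many
  distinct benign-tissue concepts.  This generator's positive class
  (dense nuclei rendered at three SLIC granularities) produces about as
  many stable concept clusters as its negative class, so which class
  holds the majority of significant concepts is a small-margin event;
  the corresponding seed-replication check is expected to fail here even
  though the saturation and purity signatures reproduce exactly.  For
  the same reason the dominance instrument can fire spuriously on
  unbiased controls, so the control property test asserts only the
  marker and purity instruments.
* The patch-center "dataset bias" design is excluded by construction:
  concept patches carry no location context, so a purely positional
  bias is invisible to this method.
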