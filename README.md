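# xbias — do concept explanations actually find dataset bias?

A deep tile classifier for histopathology can score perfectly and still
be wrong in every way that matters: it may have keyed on a scanner's
colour cast, a slide contaminant, or a skewed sampling of tissue types
rather than on disease morphology.  This package is a controlled,
fully synthetic validation study of two explanation families as
*bias-discovery* tools:

* **ACE + TCAV** — automated concept extraction (SLIC superpixels →
  FC-layer embeddings → k-means concepts) scored with concept
  activation vectors;
* **(Guided) Grad-CAM** — class-discriminative saliency maps.

It is aimed at researchers evaluating explainable-AI methods for
digital pathology, and at anyone who wants a reproducible, planted-bias
benchmark where the ground truth of "what the model actually used" is
known by construction.

## The pipeline

1. **Synthetic tiles** (`xbias.synthgen`): two-class histology-like
   tiles (nucleus density/size is the class signal), virtual slides
   with per-slide stain jitter, slide-disjoint splits, and four planted
   biases — class-ratio (≈2:1 rejection sampling), measurement (label
   confounded with a brighter/flatter source regime), sampling
   (collagen stratum removed from training negatives), class-correlated
   (red square on every positive tile).
2. **Classifier** (`xbias.cnn`, `xbias.nn`): a small residual CNN
   (7×7/32 stem, 2×[3×3,32] + 3×[3×3,64] residual blocks, global max
   pool, 16-d FC, softmax; Swish activations) trained with Adam
   (lr 2·10⁻⁴, batch 32), flip/rotation/cutout-127 augmentation, class
   weights, checkpointing and early stopping — implemented directly on
   numpy with analytic, finite-difference-tested backprop.
3. **Explanations** (`xbias.ace`, `xbias.tcav`, `xbias.saliency`):
   multi-resolution SLIC concept patches on grey-127 canvases, k-means
   concepts, CAVs from a linear SVM vs fresh random counterexamples,

       TCAVQ = |{x ∈ X_k : ⟨∇h(x), v⟩ > 0}| / |X_k|,

   significance by Welch t-test against random-vs-random null CAVs over
   repeated runs (α = 0.01); Grad-CAM `ReLU(Σ_k α_k A^k)` with
   `α_k = mean ∂y/∂A^k`, guided backprop, and their pointwise product.
4. **Bias checks** (`xbias.experiments`): operational flags — marker
   overlap ≥ 0.9 of a significant positive concept, source purity 1.0
   of a significant concept, dominance shift of significant concepts
   toward the absence-defined negative class — plus paired
   biased-vs-unbiased metric comparisons.

See `docs/methods.md` for the model, the scoring maths and every
numerical choice.

## Worked example

Train and explain the two shortcut-bias models at desk scale (96 px
tiles, 30 slides × 40 tiles; roughly 15 minutes on one CPU):

```bash
python analysis/02_shortcut_biases.py --seed 1 --out results
```

prints, for the class-correlated (red-square) configuration:

```
== class_correlated: balanced accuracy 0.966, AUC 1.000
   bias flags: {'dominance_shift': False, 'marker_concept': True, 'source_purity': False}
   significant concept 0 -> class 0: TCAVQ 1.00 ± 0.00
   significant concept 2 -> class 0: TCAVQ 1.00 ± 0.00
   significant concept 3 -> class 1: TCAVQ 1.00 ± 0.00
   significant concept 4 -> class 1: TCAVQ 1.00 ± 0.00
```

Reading: the classifier looks essentially perfect on the held-out split
(AUC 1.0) — but the two significant positive-class concepts score
TCAVQ 1.0 ± 0.0 and their patches are, on inspection of the gallery
PNGs, the planted red square (marker overlap 1.0 in `report.json`).
The `marker_concept` flag fires: the "perfect" model is a shortcut
detector.  The measurement run behaves the same way with a source-pure
significant concept instead (`balanced accuracy 1.000, AUC 1.000`,
`source_purity: True`), and the Grad-CAM triptychs show the coarse map
concentrating on the marker square.

The distribution biases are direction checks rather than saturation
checks:

```bash
python analysis/03_distribution_biases.py --seed 1 --out results
python analysis/04_summary.py --out results
```

reports the paired degradation `class_ratio: biased AUC 0.407 vs
unbiased 0.769 (degraded)` and the sampling-bias concept-dominance
fractions (see the caveat on this signature in `docs/methods.md`), then
collects everything into `results/summary.csv`.

## Practical notes

* k for k-means is experiment-specific (`ACEConfig.k`, default 5):
  duplicate-looking concepts mean k is too large, mixed/incoherent
  concepts mean it is too small.
* TCAV significance needs ≥ 20 runs; with fewer, a perfect concept
  cannot reach α = 0.01 against a binary null.
* The cutout-127 augmentation is required for meaningful concepts: the
  grey canvases of concept patches are otherwise off-manifold for the
  network.
* The patch-center "dataset bias" design is rejected by
  `run_experiment` on purpose — location-only biases are invisible to
  cropped concept patches; use the saliency maps for those.
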