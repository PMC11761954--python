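# Methods

## Scope and data model

The package implements a two-stage, per-task predictor of binary glioma
genetic events from H&E image patches, plus the surrounding protocol:
tiling, augmentation, per-task cross-validation, DeepLIFT interpretation,
and the WHO-2021 integrative decision tree. The unit of supervision is the
**case**: a case has one or more slides, a slide contributes ~40–50 retained
256×256 patches at 0.5 µm/px, and every patch inherits its case's binary
status for the task at hand (weak supervision). Label availability differs
per task, so folds and cohorts are constructed independently per task.

## Tiling

Slides are cut on a non-overlapping grid with stride 256, anchored at the
origin of the ROI bounding box (slide origin without an ROI). Tiles are
half-open `[x, x+256) × [y, y+256)` in 0-based, top-left-origin, level-0
pixel coordinates. A tile is whitespace when **all three** channels are at
or above `white_threshold` (default 220, a common tissue-mask heuristic;
configurable); tiles with more than 50 % whitespace are discarded. When a
slide yields more than `max_patches_per_slide` (default 50) tiles, a seeded
uniform subsample of exactly 50 is kept — a hard, reproducible version of
"approximately 50 per slide". When the native resolution differs from
0.5 µm/px the image is bilinearly resampled first and reported coordinates
are mapped back to level-0 pixels. Slides with fewer than K = 32 retained
patches still form fixed-size bags by sampling with replacement; these are
logged as degenerate. ROIs (GeoJSON polygons or PNG masks) are taken as
given; a tile is inside the ROI only if fully contained.

## GLISP-P (patch model)

Four convolutional blocks (3×3 kernels, stride 2, ReLU), global average
pooling, and an MLP head ending in a sigmoid. Package defaults: a fixed 2×2
average-pool stem, channels 3→8→16→32→64, MLP 64→64→1, encoding_dim 64. The
penultimate MLP activation (64-d) is the patch **encoding**. These constants
are deliberately small — the design premise is one cheap, independently
trainable and interpretable model per genetic task, sized so the full
two-stage pipeline trains in minutes on a single CPU core — and all of them
are configurable (`GlispPConfig`), including disabling the pooling stem.
Wider settings behave identically but cost proportionally more.

Inputs are mapped to `x/255 − 0.5`. Training uses Adam (lr 1e-4, batch 64,
up to 20 epochs), binary cross-entropy on logits with inverse-prevalence
class weights, an early stop on validation loss (patience 3), and a
stratified case-level holdout (20 %) — an assertion guarantees no case
appears on both sides. One top-level seed fans out to named substreams for
splitting, shuffling, augmentation and weight initialisation, so training is
bit-reproducible.

**Augmentation** follows the mixed-distortion protocol: with probability
p = 0.5 a training patch receives a random quarter-turn rotation and flips,
colour jitter (brightness/contrast/saturation ±0.2, hue ±0.05) and Gaussian
blur (σ ~ U(0.1, 1.5)). No stain normalisation is applied anywhere — the
framework treats it as unnecessary for this problem. With p = 0 the
operation is a byte-identical no-op, which the tests rely on.

## GLISP-W (slide MIL model)

A bag is K = 32 encodings drawn without replacement from one slide's
patches. MLP1 (64→64, ReLU) transforms instances; the standard (non-gated)
attention scorer `s_k = wᵀ tanh(V h′_k + c)` (attn dim 32) is softmaxed into
convex weights; MLP2 (64→32→1, sigmoid) maps the pooled vector to the slide
probability. A gated variant (multiplicative sigmoid branch) is available by
config. Forward/backward are hand-derived NumPy in float64; permutation
invariance is exact up to floating-point summation order (contracted at
1e-6 in the tests), and with K = 1 the model reduces exactly to MLP2∘MLP1.

Training resamples **fresh bags every epoch** (4 draws per slide per epoch
by default), which acts as bag-level augmentation and, on cohorts of a few
hundred slides, supplies enough optimisation steps for Adam (lr 2e-3, batch
16, up to 60 epochs, patience 10). The validation loss is averaged over 4
independent bag draws to de-noise early stopping. The patch model is frozen
throughout (two-stage design; end-to-end fine-tuning is out of scope).

Slide-level prediction averages the bag probability over R = 8 seeded bag
draws; case-level prediction averages slide probabilities (the mean policy
is a package choice — multi-slide pooling is otherwise unspecified).
Increasing R from 8 to 64 moves synthetic case AUCs by well under 0.02.

## DeepLIFT interpretation

Attributions use the rescale rule against a reference input: affine layers
(conv, linear, average pooling) propagate multipliers exactly like input
gradients; elementwise nonlinearities use Δout/Δin, falling back to the
derivative when |Δin| < 1e-7. On networks without multiplicative
interactions this satisfies summation-to-delta (Σ attributions =
f(x) − f(reference)) to floating point, which is asserted on random ReLU
networks at 1e-3 relative tolerance. The reference is the per-dataset mean
patch (fallback: all-white). Per-channel pixel attributions are summed over
RGB; the patch-level score is the arithmetic mean of all pixel scores; patch
ranking breaks ties deterministically by (slide_id, x, y). The attributed
output is the event probability by default (the sigmoid is handled exactly
by the rescale rule); the logit is available by option.

## Diagnostic workflow

The decision tree composes six marker slots {IDH, 1p/19q, CDKN2A/B-del,
TERTp, EGFRamp, 7+/10−} — each either a thresholded model probability
(default operating point 0.5, boundary = positive; optional Youden-J
calibration on a validation split) or an assay result that bypasses
thresholds entirely — with MVP/necrosis flags. Rules: IDH-mut ∧ codel⁺ →
oligodendroglioma (grade 2/3 by histology, reported "undetermined");
IDH-mut ∧ codel⁻ → astrocytoma, grade 4 iff CDKN2A/B-del⁺ ∨ MVP ∨ necrosis;
IDH-wt → glioblastoma iff any GBM genotype ∨ MVP ∨ necrosis, else "diffuse
glioma NOS" (that leaf is a package naming choice). codel⁺ under IDH-wt is
contradictory (co-deletion is only meaningful in IDH-mutant tumours) and
returns NOS with the contradiction in the rationale trail. The tree is total
over all 2⁶ × 4 combinations and every consulted rule is recorded.

The three-class molecular call (astrocytoma / oligodendroglioma /
glioblastoma) uses only the IDH and 1p/19q probabilities; co-deletion is
ignored under wildtype IDH. Clinical contexts: (1) IDH-wt cases →
TERTp/EGFRamp/7+/10− (reported with NPV, since ground-truth positives can be
absent in this stratum); (2) IDH-mut → CDKN2A/B deletion; (3) IDH-mut →
1p/19q co-deletion.

## Evaluation protocol

ROC AUC uses the midrank (Mann–Whitney) formulation; accuracy, F1,
precision, recall and NPV = TN/(TN+FN) at threshold 0.5. Confidence
intervals are nonparametric percentile bootstrap over cases (B = 2000,
seeded); degenerate one-class resamples are skipped and logged. The CI
method is a package choice — no particular construction is mandated by the
protocol being reproduced. Cross-validation is stratified at case level,
independently per task, with k = 5 by default; stratification relaxes to
plain K-fold with a warning when a class has fewer members than folds. 3×3
confusion-matrix metrics declare their axis semantics explicitly; overall
accuracy and per-class F1 are invariant under transposition (precision and
recall swap), which makes the bundled external-validation matrix — whose
axis labelling is ambiguous in its source — safe to report. Metrics are kept
at full precision internally and rounded to 2 dp only in rendered reports.

## Synthetic data

A patch is an "eosin" pink base modulated by two smoothed Gaussian random
fields (coarse and fine), with "hematoxylin" purple nuclei-like blobs
(radius 3.2–6 px) placed on a jittered grid (blue-noise-like spacing; a
cheap, exactly seedable stand-in for dart-throwing Poisson-disc placement)
plus white pixel noise. The background stays below the whitespace threshold
by construction, so every generated patch passes the tiling filter. A
positive case's witness patches (an exact rounded fraction `witness_rate` of
its patches, at least one) get blob occupancy scaled by (1 + 0.35·effect)
and blob colour shifted toward blue by effect·(−9, −4, +10) — the signal
lives in nuclei density and hue rather than global colour precisely so the
colour-jitter augmentation cannot erase it. At effect 0 the witness flag is
statistically (indeed byte-) inert.

Defaults are the conditions of the end-to-end experiments: 200 cases, 1
slide/case, 40 patches/slide, prevalence 0.5, effect 2.0, witness rate 1.0.
Determinism holds at every level via a spawned seed tree. What the generator
does **not** emulate: real histologic morphology, stain variation between
laboratories, scanner artefacts, spatial correlation between patches of one
slide, or label noise — so passing synthetic tests demonstrates the
learning machinery and its hygiene (no leakage, no null discrimination),
not clinical performance.

## Experiment scales

The bundled experiments are sized for a single CPU core: the strong-signal
run uses the generator defaults (200 cases × 40 patches, 5 epochs, 70/30
case split); the null run uses 400 cases × 20 patches with a 50/50 split so
that a chance-level bag AUC has small enough sampling error for the
[0.40, 0.60] acceptance band (~2.5 σ); the partial-witness run (test suite)
uses 80 cases × 24 patches at witness rate 0.25. Together they finish in
roughly 10–15 minutes.

## Numerical choices and limitations

* float32 for the CNN (im2col + single-GEMM convolution; backpropagation
  stops below the first trainable layer), float64 for the MIL model and
  DeepLIFT multiplier propagation.
* Stable BCE on logits; sigmoid evaluated in its overflow-safe split form.
* Hue jitter is implemented as a linear rotation of the YIQ chroma plane
  (the classic hue-rotate operator); Gaussian blur kernels are truncated at
  2.5 σ. The fixed pooling stem is fused into input preparation for
  training/inference (pooling and the affine normalisation commute); the
  attribution path keeps the stem explicit so maps stay full-resolution.
* Softmax attention subtracts the row max before exponentiation.
* Ties in patch ranking and in the tiling subsample are resolved by sorted
  provenance/index, never by dict order.
* The whitespace boundary is inclusive (a pixel equal to the threshold
  counts as white); the marker operating point is inclusive (probability
  equal to the threshold is positive). Both are documented conventions, not
  tunables.
* Known limitations: no pyramidal-WSI backend (PNG/JPEG/TIFF only); no
  stain normalisation or color transfer; no end-to-end fine-tuning of the
  two stages; no multi-gene cross-attention; histologic grade 2 vs 3 is
  outside the model's inputs and reported as "undetermined".
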