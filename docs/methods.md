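# Methods

`wsiweak` implements weakly supervised whole-slide image (WSI)
classification: assigning one of three labels — non-cancer (NC),
adenocarcinoma (ADC), squamous cell carcinoma (SqCC) — to a slide using
only slide-level diagnoses as supervision, together with every baseline
family the approach is usually compared against. This note records the
models, the assumptions behind the synthetic corpus, the numerical
choices, and what the desk-scale experiments do and do not demonstrate.

## The classification problem and the two weak-supervision routes

A digitised slide is orders of magnitude larger than the inputs
convolutional classifiers are designed for, and lesions may occupy a tiny
fraction of the tissue. Two families of methods work from slide-level
labels alone:

**Multiple-instance learning (MIL).** The slide is a *bag* of 224×224
tiles (*instances*); a bag is positive iff at least one instance is
positive. Training alternates (i) scoring every instance with the current
classifier and (ii) optimising the classifier on a selected subset: the
top-k instances of each cancerous bag inherit the slide label, and benign
bags contribute k random instances labelled NC (the negative-bag rule of
the binary formulation, mapped to the benign class; random subsampling
keeps the selected set balanced — the convention for negative bags is our
choice, the protocol being silent). Bag inference max-pools instance
scores: each cancer class takes its instance maximum, the benign score is
the instance minimum of the benign probability, and the triple is
renormalised. On top of this sit the published aggregation variants:

* **EM selection (EM-CNN-LR / EM-CNN-SVM)** — instead of a fixed k, the
  per-class tile prediction map is blurred with a 3×3 Gaussian (σ = 1,
  masked normalisation so background cells do not dilute tissue cells)
  and tiles are selected when their blurred score strictly exceeds an
  image-level or a class-level percentile threshold. Both thresholds are
  exposed as top-fraction parameters: the published "0.1th-percentile /
  0.05th-percentile" wording is ambiguous about the tail, so the
  parameters are configurable and desk-scale runs use larger fractions
  (slides here hold tens of tiles, not tens of thousands). The slide is
  then represented by its class histogram — the component-wise sum of all
  tile probability triples — fed to a logistic regression or RBF-SVM bag
  classifier.
* **CNN-MaxFeat + random forest** — the pre-head embeddings of the k = 3
  highest-scoring tiles (ranked by best cancer probability) are averaged
  and classified by a random forest; the instance model is the standard
  MIL (k = 3) classifier.
* **MIL-RNN** — the top-k embeddings, in descending score order (an
  ordering convention; the protocol does not state one), drive a 128-unit
  tanh recurrent network whose final hidden state maps linearly to the
  3-way softmax. Trained by Adam with backpropagation through time.

**Whole-slide training.** The alternative is to feed the *entire*
(downscaled, white-padded) slide through the CNN in one pass and train
end-to-end from the slide label. The final feature map then has many more
cells than the 7×7 a 224-px input produces, and each cell still only sees
one receptive field. With **global average pooling (GAP)** the few cells
covering a small lesion are averaged with hundreds of irrelevant ones and
the training signal dilutes; replacing GAP by **global max pooling
(GMP)** keeps, per channel, only the strongest activation, so a single
receptive field covering the lesion suffices — the MIL "max" assumption
embedded inside the network head. The loss is the 3-class categorical
cross entropy
`L = −y_NC ln ỹ_NC − y_ADC ln ỹ_ADC − y_SqCC ln ỹ_SqCC`
with predictions clipped to [1e−12, 1] before the logarithm.

## Receptive-field calculus

For the sliding-window layers along the downsampling path, receptive
field `r` and cell spacing (`jump`) `j` propagate from `r = j = 1` as
`r ← r + (k−1)·d·j`, `j ← j·s`. Residual blocks contribute through their
longest branch. For the reference ResNet-50 description the recurrence
gives `r = 483` px — note this requires the original (v1) placement of
the stage's stride-2 on the *first 1×1* convolution of the leading
bottleneck; the common v1.5 variant (stride on the 3×3) yields 427 and is
not what the published figure describes. Output sides follow the
same-padding rule `out = ceil(in/s)`: 224 → 7 and 21 500 → 672. Physical
field sizes are `r · µm/px`, rounded to the micron: 222 µm at ×20
(0.46 µm/px), 1111 µm at ×4, 2222 µm at ×2. The recurrence is verified in
the tests against brute-force gradient-support probing (which input
pixels can influence a chosen output cell) on random small architectures.

## Localisation

Class activation mapping (CAM) contracts the final feature map against
the dense-layer weight row of the class of interest,
`heat = Σ_c W[c, class]·fm[:, :, c]`, min-max normalises per slide, and
upscales bicubically to the slide extent. The original CAM derivation
assumes a GAP head; the same formula is applied under GMP — the map still
scores how strongly each location would drive the class logit, but values
at non-argmax cells did not contribute to the actual prediction, a
documented semantic caveat. MIL prediction maps (per-tile probabilities
on the tile grid, background cells zeroed) are upscaled the same way for
comparison. `localization_overlap` binarises a heatmap at a threshold and
reports pixel precision/recall against the lesion mask within tissue; it
is a construction of this package for quantifying localisation on
synthetic slides, with no published counterpart value.

## Memory-group scheduling

Training on inputs far beyond accelerator memory relies on paging device
memory from host memory; naive on-demand paging thrashes. The planner
implements the two published optimisations abstractly: *Group Execution*
(topologically sort the operation graph — deterministic Kahn ordering,
ties by id — then cut greedy maximal prefixes whose summed
intermediate-tensor bytes fit the budget; an op larger than the budget
becomes a warned singleton) and *Group Prefetch* (control edges serialise
groups; one explicit-copy prefetch per upcoming group is issued during
the preceding group). The transfer simulator compares on-demand paging
(serialised with compute, default 3.6 GB/s) against overlapped explicit
copy (default 10.3 GB/s, per-slot cost `max(compute, next prefetch)`);
with an explicit rate at least the on-demand rate the prefetch schedule
is provably never slower, and the tests check this on random graphs.
Times are simulated, never measured; only intermediate tensors are
counted against the budget (weights are assumed resident).

## Evaluation statistics

Per-class scores come from one-vs-rest binarisation of the ternary
softmax (the score for class c is its probability; no renormalisation).
AUC is the Mann-Whitney statistic with ties counted ½. Variance uses
DeLong's structural components (midrank formulation); the 95% CI is the
normal approximation clipped to [0, 1], degenerating to a width-0
interval with a warning under perfect separation. Paired model comparison
is the two-sided DeLong z-test with the paired component covariance.
Bootstrap summaries resample cases with replacement (degenerate
resamples are redrawn so the iteration count stays exact, 100 by
default) and report quartiles and whiskers at the
`Q2 ± 1.5·(Q3 − Q1)`-clipped-to-observed convention.

## The synthetic corpus

Real slides are mostly white glass plus one or two compact tissue
sections; cancerous slides contain lesion regions whose texture differs
from benign parenchyma, and benign tissue contains structures that *look
partially* cancerous (hyperplasia and similar mimics — the very regions
blamed for trapping instance selection). The generator reproduces that
skeleton on a 512×512 canvas at 2.3 µm/px (the ×4-equivalent working
magnification):

* **Background** is exactly 255 on all channels, so the standard
  background filter (drop a tile iff *every* pixel of *every* channel is
  strictly above 220) applies unambiguously; tissue pixels are clipped to
  ≤ 219 so no tissue tile is ever discarded.
* **Tissue** is one compact organically shaped region (smoothed noise
  field minus a radial penalty, thresholded at the exact area quantile),
  covering a per-slide fraction drawn from U(0.2, 0.4) — chosen so the
  background filter removes roughly the published four-fifths of tiles
  when measured on a grid fine enough that boundary tiles are a minority.
* **Lesions** (ADC and SqCC) are compact regions grown to an exact pixel
  count around an interior seed, so the lesion/tissue area ratio equals
  the requested `lesion_fraction` up to mask rounding. Class palettes
  (purple-shifted for ADC, red-shifted for SqCC) differ from benign
  tissue by ~40-60 mean-channel units against a noise σ of 8, making
  tiles linearly separable by mean colour — deliberately, so desk-scale
  runs test the *training machinery* rather than feature learning.
* **Distractors**: every slide, benign ones included, carries two kinds
  of benign mimic. *Blob mimics* are compact regions whose colour is the
  tissue palette moved 35-50% of the way toward a cancer palette
  (alternating between the ADC and SqCC directions), totalling 8-18% of
  tissue area: their peak intensity stays well below a true lesion (a
  max-pooled detector can threshold them out) while their integrated
  colour shift overlaps the signal of a small lesion. *Micro-speckles*
  are scattered 1-3 px dots carrying the full lesion palettes with
  per-dot colour offsets matching lesion-texture extremes, totalling
  2-6% of tissue: individually they cover a small fraction of any
  receptive field, so no pixel-level colour threshold and no single
  feature-map cell separates them from lesion tissue — only spatial
  extent does. Together they put benign slides exactly in the regime
  where averaged slide evidence, and max-rule MIL inference over benign
  tiles, become unreliable while max pooling over full receptive fields
  stays clean.
* **Corpus structure**: balanced classes; an exact quota (default 30%)
  of each cancer class is generated in the small-lesion regime
  (`lesion_fraction` < 0.10, drawn from U(0.02, 0.10); the remainder from
  U(0.10, 0.40)). Per-slide seeds derive from the corpus seed. Stratified
  splitting uses largest-remainder rounding per label stratum.

What the generator does **not** emulate: H&E stain statistics and stain
variation, scanner artefacts, nuclear/cellular morphology, pyramidal file
formats, multi-site colour shifts, frozen-section artefacts. Passing
desk-scale tests therefore demonstrates the correctness and the relative
behaviour of the training machinery under controlled small-object
statistics, not clinical-grade performance on real tissue.

## Desk-scale configuration

All methods run on one CPU within minutes using a deliberately small
backbone and working resolution; every algorithm is side-agnostic, so the
same code paths apply to the reference configuration.

| Parameter | Reference protocol | Desk scale | Why |
|---|---|---|---|
| backbone | ResNet-50, 2048 channels | 3 × (3×3 stride-2 conv + ReLU), channels (8, 16, 32) | minutes-scale CPU training; rf 15 px / jump 8 px |
| init | fixup / pretrained | He-style from-scratch | no downloads; acceptance never depends on init choice |
| whole-slide input | pad to 21 500² (×4); input/rf ≈ 44 | native 512² (the corpus is generated at the ×4-equivalent working magnification); input/rf ≈ 34 | the pooling-head comparison only probes the published regime when the input dwarfs the receptive field — at 128² (input/rf ≈ 8.5) average pooling is barely diluted and the GMP/GAP contrast does not manifest |
| tiles | 224² at ×4 | 224² cut, downscaled to 56² for the instance CNN | keeps the published tile geometry while shrinking compute |
| optimiser | Adam, 2e-5 → 2e-6, patience 24, 100 steps/epoch, batch 8 | Adam, 1e-3 → 1e-4, patience 5, 50 steps/epoch, batch 8; 10 epochs for whole-slide models (both heads, identical budget), 15 for the instance-model family | a small from-scratch net trains at a larger rate; epoch = fixed step count and lowest-validation-loss checkpointing kept |
| augmentation | flips, translation, rotation, colour (contrast 0.5-1.5, brightness 0.65-1.35, hue ±32, value ±32) | flips during training; the full pipeline is implemented and tested | resampling-based augmentation costs more than it adds on colour-defined textures |
| corpus | 7003 slides, 3 sites; stratified 72/8/20 split | 201 synthetic slides (67/class), single site; stratified 50/10/40 split | desk-scale problem size; the enlarged test share buys rank-resolution for AUC comparisons that a ~40-slide test set cannot provide |

Aggregator details at desk scale: MaxFeat-RF and MIL-RNN rank instances
by suspiciousness (one minus the benign probability — the ternary reading
of "most likely to be cancerous"), and both fit on the train and
validation bags together; the validation split steers only the CNN's
checkpoint selection, so the slide-level aggregators are free to consume
it as extra supervision.

The `TrainConfig` defaults record the reference protocol values. The
√(#GPUs) learning-rate scaling for synchronous data parallelism is
carried as a documented, inert field (`n_gpus`; single-process
execution).

## Numerical choices

* Probabilities are clipped to [1e−12, 1] before logarithms.
* 'Same' padding follows the `ceil(in/s)` shape rule with the extra pixel
  on the bottom/right; this is the dialect that reproduces 224 → 7.
* GMP backpropagation routes the gradient to the first-occurring argmax
  cell per (sample, channel); ties are measure-zero for real data.
* Top-k selection breaks score ties toward the lowest row-major index
  (stable argsort on negated scores).
* EM selection uses strict `>` against linearly interpolated quantiles:
  a uniform map selects nothing.
* Hue arithmetic wraps modulo 256 (hue is circular); value shifts clip.
  Contrast scales RGB deviations about the per-image mean. Geometric
  augmentation fills exposed area with white (255) to stay consistent
  with the background filter.
* Downscaling is bilinear (the interpolation kernel is not specified by
  the protocol; isolated behind the `downscale` function).
* All randomness flows from integer seeds through `numpy` Generators;
  experiment runs derive named sub-seeds (corpus/split/train/aggregator)
  from the config seed via `SeedSequence` and record them in the report,
  making reruns byte-identical.

## Known limitations

* The numpy CNN is minutes-fast at desk scale but not a platform for
  real-resolution training; the memory scheduler is an abstract planner,
  not a CUDA integration.
* CAM under a GMP head highlights what *would* drive the logit
  everywhere, not only at the argmax cells that did.
* Desk-scale AUC comparisons across methods rest on ~40 test slides;
  orderings are directional properties of the configured corpus, and
  single-slide rank flips move an AUC by ~0.03-0.08. Published headline
  AUCs require the original 7003-slide corpus and are out of reach by
  construction.
* The EM percentile thresholds are corpus-size-dependent; the desk-scale
  defaults are far larger than the published fractions because slides
  here hold tens of tiles rather than tens of thousands.
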