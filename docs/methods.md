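# Methods

## Problem and model

The package classifies subjects as healthy aging controls or as having mild
cognitive impairment (MCI) from three drawings — a clock face drawn to
instruction, a copied Necker cube, and a trail-making path connecting
alternating numbers and letters — together with the subject's MoCA
screening score (0–30), which defines the diagnostic label.

Each task image (resized to a square input, grayscale replicated to three
channels, represented *ink-positive*: paper = 0, full ink = 1) is encoded by
its own CNN backbone. The backbone's last feature map `X ∈ R^{H×L×C}` is
projected channel-wise (1×1 convolution) to the attention hidden dimension
`D`, flattened row-major (token `1 + r·L + c` ↔ grid pixel `(r, c)`), and
prefixed with a learned CLS vector. A stack of single-head self-attention
encoder layers — scaled dot-product attention `softmax(QKᵀ/√D)V`, residual
connection, layer norm, GELU feed-forward sublayer, layer norm (the
standard post-LN encoder block) — aggregates the tokens. The attention
output is added directly to the residual stream without an output
projection, matching the residual form `V_{l+1} = V_l + W_att·V_l` that the
rollout compensation assumes. The three final CLS vectors are concatenated
and mapped by a two-node affine + softmax head to `(p_healthy, p_MCI)`;
`p = p_MCI` is the model output and `p ≥ 0.5` the decision rule.

Targets are hard labels `1[m < cutoff]` (cutoff 25) or soft labels
`y = 1 − σ(m − 24.5)`, and the loss is mean binary cross-entropy with
predictions clamped to `[1e−7, 1 − 1e−7]`. Optimization is Adam; the
reference settings are learning rate 1e−5, β₁ = 0.9, β₂ = 0.99, ε = 1e−7,
100 epochs, batch 64, which suit fine-tuning a pretrained backbone at
256×256.

The comparison baseline replaces projection + attention with global average
pooling of the last feature map, keeping everything else identical.

### Backbones

* `vgg16`: the 13-conv/5-pool VGG16 feature-extractor configuration
  (8×8×512 map at 256×256 input). Weights are He-initialized; externally
  trained weights can be injected by assigning parameter arrays, but
  nothing in the package requires them.
* `toy`: four conv3×3+ReLU+maxpool blocks with channels (8, 16, 32, 32),
  giving a 4×4×32 map at 64×64 input. This is the desk-scale backbone used
  throughout the tests and the synthetic study.

All networks, including the autodiff engine and Adam, are NumPy
implementations inside `cogdraw.nn`; float32 throughout, deterministic
given the seed and single-threaded BLAS.

## Interpretability

Per layer, the row-stochastic attention matrix `W_att` over the
`HL + 1` tokens is recorded. The raw attention `A = 0.5·W_att + 0.5·I`
compensates for the residual path, and the rollout is the ordered product
`Ã(l_i) = A(l_i)·Ã(l_{i−1})` with base case `Ã(l_j) = A(l_j)`; reported
heat maps always roll out across the whole stack. The CLS row (column 0
dropped) is reshaped to `H×L` — the exact inverse of tokenization — and
upsampled bilinearly to the input resolution. Grad-CAM (channel-wise
gradient-weighted sum of the last feature map, rectified, upsampled) serves
the pooling baseline; its target class defaults to the MCI logit.

Heat maps are compared to binary regions of interest via top-k%
binarization (exactly `round(k/100 · n_pixels)` ones, ties broken by linear
pixel index for determinism) and IoU `|A∩B|/|A∪B|` (defined as 0 for two
empty masks). Two ROI families are supported: *whole-drawing* ROIs — the
minimal enclosing circle, ellipse (Khachiyan minimum-volume ellipse), or
convex polygon around all ink pixels (ink = intensity below 0.5 of white,
configurable), dilated by a margin of 5 px by default — and *expert* ROIs,
masks over anomalous or missing strokes; for synthetic cohorts these are
the generator's anomaly masks, for real data user-supplied mask files.

## Synthetic cohorts

The generator emulates the three drawing tasks as anti-aliased dark strokes
on white canvas with a fixed canonical layout (deterministic geometry, only
sub-pixel digit jitter varies with the seed). A per-subject severity
`s ∈ [0, 1]` controls

* defect injection per task: the defect count is Binomial(4, s) drawn from
  a per-task catalog (clock: misplaced hand, missing digit, duplicated
  digit; cube: broken edge, stray edge; trail: wrong connection, omitted
  connection), with defect size growing mildly with severity. Every defect
  is logged with a binary mask covering the modified pixels — or, for
  omissions, the locus where the erased element should have been;
* the score `clip(round(30 − 12·s + ε), 0, 30)` with ε ~ N(0, noise_sd).
  The slope 12 puts severity 0.5 at score 24, just below the cutoff 25, so
  the label boundary falls mid-range where soft labels matter most.

Because the base drawings are class-constant, all class signal lives inside
the anomaly masks — which is what licenses using those masks as ground
truth for localization scoring. This is also the generator's main
departure from real data: real drawings vary in style, stroke quality and
placement between subjects, and real abnormality is not a superposition of
discrete stamped defects. Passing tests on synthetic cohorts therefore
demonstrate that the pipeline recovers a planted severity mechanism, not
that the model reaches clinical accuracy.

## Data handling

Manifests are CSV (subject id, three image paths, optional mask paths,
MoCA score, optional severity). Images of any resolution are plainly
rescaled (bilinear, no aspect-ratio padding) to the working size.
Stratified 70/15/15 splitting rounds the validation and test strata
half-up per class and gives the remainder to training — with 651 healthy /
267 MCI this yields the 98 + 40 = 138-subject test partition.
Augmentation zero-pads by `size·12/256` pixels per side and crops back at a
random center (the classic 256→280→256 scheme, scaled to the working
resolution); in ink-positive representation the padding adds nothing and
ink mass can only shift or fall off the edge. Augmentation applies to
training images only; evaluation always uses the deterministic center.

## Scaled-down synthetic study

`cogdraw.experiments.scaled_synthetic_study` is the package's
self-validation experiment, sized for a single CPU: 300-subject cohorts
(severity ~ Uniform[0, 1], score noise sd 1) at 64×64, three repeated
stratified splits, and the toy backbone with D = 32, ffn 64, two encoder
layers. From-scratch training uses Adam at learning rate 1e−3, batch 16,
30 epochs, best-validation-AUC checkpoint; translation augmentation is
disabled because the synthetic layout is canonical, so the jitter only adds
gradient noise. AUC/accuracy/F1 are averaged over the repeats (the same
repeated-splits protocol used for reported cohort metrics); localization
pools all test images with nonempty anomaly masks and compares each
top-20% binarized rollout heat map against a per-image permutation null
(grid-level spatial shuffles of the same map, 10 draws averaged).

Observed behavior, reproducible via `scripts/acceptance.py`: the
multi-input model reaches held-out AUC ≈ 0.9 and is never more than
sampling tolerance below any single-input variant, and rollout heat maps
overlap anomaly masks about twice as well as the permutation null on
average. The per-image win rate against the null is, however, only ≈ 0.6–0.75:
with a class-constant base drawing, the total ink count is already a
sufficient statistic for severity, so uniform CLS attention plus
value-pathway coding is loss-optimal and nothing forces the attention map
to localize on every image. Sharper attention can be induced (e.g. by
scaling the query/key initialization), but in our experiments it traded
discrimination for localization without making per-image wins reliable.
This is a genuine property of the model class under these study
conditions, not an implementation artifact, and is worth keeping in mind
when interpreting rollout maps on real data.

## Numerical and design choices

* Attention: single head; no positional embeddings (tokens are unordered
  plus CLS); CLS vector initialized N(0, 0.02²); encoder depth default 2
  ("a stack", and rollout is nontrivial only from two layers up).
* Softmax rows are computed with max-subtraction; attention logits scale by
  1/√D; rollout products are evaluated in float64.
* Heat-map upsampling is bilinear (`skimage.transform.resize`, order 1).
* Checkpoint selection: best validation AUC by default, final epoch by
  flag; the backbone is fully fine-tuned (never frozen).
* AUC is the rank-based Mann–Whitney statistic with ties counted ½
  (cross-checked against scikit-learn's implementation in the tests);
  F1 uses MCI as the positive class.
* Degenerate inputs: blank images are rejected by ROI construction;
  single-class test sets make AUC raise rather than return a default;
  two empty masks have IoU 0 by convention.

## Known limitations

* No pretrained backbone weights ship with the package, so `vgg16` results
  on real images will not match transfer-learning setups without injecting
  externally trained weights.
* The NumPy networks are CPU-bound and practical up to desk scale
  (hundreds of subjects at 64×64, tens of epochs); the full 256×256
  VGG16 configuration forward-propagates fine but is slow to train.
* The synthetic generator does not model handwriting style, stroke
  dynamics, or scanner artifacts; temporal (trajectory) inputs are out of
  scope.
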