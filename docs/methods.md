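# Methods

## Problem and scope

Phase-contrast micro-CT of an intact rodent pancreas yields a stack of
thousands of grayscale reconstruction slices in which islets of
Langerhans appear as compact, slightly brighter inclusions on a textured
background crowded with confounders (vessels, exocrine tissue).  The
pipeline in this package (a) segments islet pixels slice by slice with a
convolutional encoder–attention–decoder network, (b) reconstructs 3-D
islets by linking per-slice components across neighbouring slices, and
(c) quantifies islet counts, volumes and size distributions.  Every
stage is exercisable end to end on synthetic phantoms with exact ground
truth, so no scan data is required to validate the implementation.

## Segmentation network

The network is a U-Net-shaped encoder–decoder with two distinctive
elements.

**Twin-block encoder.**  A shortcut-free (SF) block — two rounds of
3×3 convolution, batch normalisation, ReLU — sits at the beginning and
end of the encoder; four residual blocks (the same body plus an additive
identity shortcut, 1×1-projected on channel change) sit in the middle,
each followed by 2×2 max pooling.  The bottleneck is therefore 1/16 of
the input resolution; inputs must have sides divisible by 16.  The
residual sum is taken after the second activation, so the residual and
shortcut-free blocks differ by exactly the shortcut path — a relation
the tests exploit.  Default channel widths double per pooled stage
(base, 2·base, 4·base, 8·base).

**Affinity-aware attention bottleneck.**  Three 1×1 convolutions project
the C-channel bottleneck map to C′ = max(1, C/8) query, key and value
channels.  With pixels flattened to N = H·W columns, the affinity
W = QᵀK scores every pixel pair, a row-softmax (max-shifted for
overflow safety) turns each row into weights that sum to 1, and the
weighted feature H′[c, i] = Σⱼ A[i, j] V′[c, j] mixes every pixel's
value feature into every output pixel.  H′ is reshaped back to
C′×H×W, concatenated with the input map, and fused to C channels by a
final 1×1 convolution.  Compact matrix notations of this aggregation
(e.g. "H′ = AV′") are dimensionally ambiguous; the implementation uses
the standard non-local convention above — each output pixel aggregates
over all pixels with its own attention row — so that every pixel's
feature is influenced by all others.  The module
refuses spatial maps above 4096 pixels: the N×N affinity is meant for
the bottleneck (N = 64 for 128-pixel patches), not full-resolution maps.

The decoder mirrors the encoder: four 2×2 stride-2 transposed
convolutions, each concatenated with the pre-pool encoder feature of the
matching resolution (skip connections; disableable by config), followed
by an SF-style double convolution.  A 1×1 convolution and a sigmoid
produce the per-pixel islet probability.

An *ablated twin* (`use_attention=False`) replaces the attention module
with the identity and is used to measure what the attention contributes;
it has strictly fewer parameters.

**Numerical engine.**  The network runs on a small reverse-mode autodiff
core written for this package (`isletseg.autograd`, `isletseg.layers`):
tensors wrap NumPy arrays, every primitive (im2col convolution,
transposed convolution, max pooling, batch normalisation, softmax,
batched matmul, the pointwise ops) carries a hand-written backward pass,
and gradients were verified against central finite differences in
float64 to ~1e-7 relative error.  Parameters are float32; He
initialisation from a caller-supplied seeded generator makes
construction, training and inference bit-reproducible.

## Training

The loss is `L = L_w + L_r` with

    L_w = Σ_i [ α (−t_i log p_i) + (1−α)(−(1−t_i) log(1−p_i)) ],
    α   = |t₋| / (|t₊| + |t₋|),

so islet pixels, which are typically below 1% of a slice, are
up-weighted by the background fraction α.  This loss is occasionally
written with a minus sign joining the two terms (treating each as a
signed log-likelihood); read literally that form is unbounded below, so
the conventional sum of two negative-log penalties is implemented —
both readings coincide when each term is understood as a penalty.  α is
computed per
mini-batch by default (a dataset-global option exists), probabilities
are clamped to [1e-7, 1−1e-7], and the sum (not mean) over pixels is
used — Adam's update is invariant to the loss scale, so this choice only
affects reported magnitudes.

`L_r` is an explicit additive L2 penalty, `weight_decay · Σ w²` over
convolution kernels (transposed included; biases and batch-norm
affine parameters excluded, the usual practice), with its gradient
2·wd·w added directly — it is *not* also applied through the optimizer,
which would double-count the same term.

Optimisation is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).  The pipeline
defaults mirror the intended full-scale regime: learning rate 1e-5,
weight decay 0.01, batch 16, up to 500 epochs, 128×128 patches cut with
stride 64 (the overlap stride is not prescribed anywhere; 50% is
standard practice).  After every epoch the model is scored on held-out
validation patches by the F-score 2·SE·PPV/(SE+PPV) at the binarisation
threshold (0.5 by default) and the best-scoring parameters are kept —
model selection is by F-score, not by loss.  Inputs are standardised
with the training set's mean and standard deviation; both constants are
stored in the checkpoint sidecar so inference reproduces them.

The *scaled-down study conditions* used by the tests and the acceptance
script: six phantom stacks of 12×128×128 voxels with four islets each
(semi-axes 4–9 px in-plane, 2.5–4 slices axially), split 4/1/1 into
train/validation/test by whole stacks, CLAHE-enhanced, cut into 64×64
patches at stride 32 and foreground-balanced to ≈260 training patches
(≈2% foreground); a base-8-channel network trained 12 epochs at learning
rate 1e-3 (Adam is scale-free, but 1e-5 is needlessly slow at this tiny
scale), weight decay 1e-5, batch 8.  These sizes were chosen once, from
a pre-build pilot, as the smallest configuration at which the network
cleanly separates phantom islets (held-out F ≈ 0.85) on a single CPU in
a few minutes.

## Pre-processing

Whole slices are CLAHE-enhanced before patch cropping (enhancement
context should exceed the patch size; applying it per patch would make
patch statistics depend on the crop grid).  CLAHE parameters are not
prescribed; the defaults are the library-common normalised clip limit
0.01 with an 8×8 tile grid, recorded in the run configuration.  Test
images are tiled into non-overlapping patches; sides that are not
multiples of the patch size are mirror-padded on the right/bottom and
the stitched prediction is cropped back.  Stitching is the exact inverse
of tiling (bit-exact round trip), and training patch grids always
include a final anchor flush with each border so edges are covered.

## Evaluation

SE = TP/(TP+FN), PPV = TP/(TP+FP), IOU = |A∩B|/|A∪B|,
F = 2·SE·PPV/(SE+PPV), and AUPR computed over all distinct probability
thresholds with step-wise (rectangular) interpolation — linear
interpolation in PR space is optimistic and is not used.  Degenerate
denominators follow an explicit convention: with empty truth, an empty
prediction scores 1 and a non-empty one 0 (configurable); empty-truth
images never occur in practice and AUPR raises on them.  The certainty
of pixel i is c_i = p_i / max_j p_j over the islet reference set; the
reference defaults to the *predicted* islet mask (certainty is used
where ground truth may be absent), with a ground-truth option.  Since
"certainty rate" is not pinned down as a scalar anywhere, the package
exports the full map and reports its mean, making the aggregation
explicit.

## 3-D reconstruction and quantification

Per-slice connected components use 8-connectivity by default (4 is an
option); centroids are arithmetic pixel means.  Components on
*consecutive* slices are linked iff their centroid distance is strictly
less than γ (default 5 px); all qualifying links are kept and closed
transitively with union–find — the rule is a pure distance predicate,
so transitive closure is the only processing-order-independent reading,
and the output is additionally sorted for determinism.  Volumes are
voxel counts × pitch³ (7.8 µm default).  Size-class thresholds are fully
parameterised and the large-islet count uses ≥ by default with a
strict-> option, because volume-class boundaries are reporting
conventions rather than physical constants; nothing is hard-coded.  Cohort
summaries report mean ± SEM (sd/√n, ddof = 1; NaN for single samples).

## Phantom generator

What it emulates: bright ellipsoidal inclusions at low contrast
(default +0.25 on a 0–1 background) with per-slice in-plane centroid
drift (uniform within a disk of radius `drift_px`, default 1.5 px —
deliberately below γ so truth masks stitch exactly); a correlated
background texture (Gaussian-filtered noise, correlation length 8 px);
elongated random-walk vessel tubes with islet-like contrast as
confounders; additive Gaussian noise (σ = 0.08); and foreground
fractions below 1%, the imbalance regime the weighted loss exists for.
A voxel is foreground iff its centre lies strictly inside the (drifted)
ellipsoid, so manifest voxel counts have a closed lattice-point
definition and the quantification recovery test is exact rather than
approximate.  Islet placement enforces in-plane separation greater than
the sum of radii plus 2γ plus drift margins, so distinct phantom islets
can neither touch nor γ-link; placement is rejection-sampled with a
finite retry budget.

What it does not emulate: Fresnel phase-contrast fringes, ring and
beam-hardening artefacts, reconstruction noise correlations, anatomy
(lobular structure, ducts), or islet shape irregularity.  Passing tests
therefore demonstrate the correctness of the pipeline's machinery and
its behaviour under the stated imbalance/contrast/drift regime — not
segmentation accuracy on real scans.

## Known limitations and open choices

* The CPU engine is practical at the scaled-down sizes used here;
  full-scale training (128-patches, 500 epochs, tens of slices of
  2048²) would want a GPU framework behind the same interfaces.
* Weight decay can act through the optimizer update or as an explicit
  loss term; the explicit-term reading was chosen because the total
  loss is defined here as a sum that includes it, and applying both
  would double-count the penalty.
* Whether the two end SF blocks change channel width is unstated; here
  the first maps input→base and the last preserves width.
* EDF support is read-only and minimal (Dim_1/Dim_2/DataType/ByteOrder,
  single image per file, payload anchored at end of file).
* The attention-vs-ablation comparison is a *paired* fixed-seed property
  check: the ablated twin is built so its encoder/decoder initial
  weights are identical to the full model's, and both are trained on
  identical batch sequences, so the measured IOU difference isolates
  the module's contribution for that seed.  At phantom scale the margin
  is small — of the same order as run-to-run training noise across other
  seeds — so it documents the direction of the effect under the fixed
  study conditions, not an estimate of a full-scale improvement.
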