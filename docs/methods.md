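# Methods

`aplscreen` implements a three-stage screening pipeline for acute
promyelocytic leukemia (APL) on peripheral-blood-smear microscopy:
leukocyte focusing, six-class leukocyte classification with a compact
channel-attention CNN, and rule-based risk stratification with a
diagnostic opinion. A synthetic stained-smear generator provides ground
truth for every stage so the whole pipeline is testable without clinical
images. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Stage 1 — leukocyte focusing (`stain_focus`)

**Model.** A Romanowsky-type stain pair is treated as a two-dye
Beer–Lambert system. Per channel, optical density is
`OD_c = -log((I_c + eps) / I0)` with `I0 = 255` and `eps = 1/255` (keeps
the log finite at 8-bit zero). A pixel's OD vector is modeled as
`OD = c_mb * v_mb + c_eo * v_eo`, where `v_mb`, `v_eo` are unit OD color
vectors for methylene blue (basic, nucleus-avid) and eosin (acidic,
cytoplasm/erythrocyte-avid). Concentrations are recovered by least squares
against the 2×3 stain matrix (right pseudo-inverse) and clipped at zero.
The default vectors — mb ≈ (0.644, 0.717, 0.267), eo ≈ (0.093, 0.954,
0.283), unit-normalized — are configurable, and `estimate_stain_vector`
fits a vector from a single-dye reference field for lab-specific
calibration.

**Color normalization.** Reinhard-style mean/std matching, by default in
CIELAB (the standard space for stain-appearance transfer), with an RGB
option. A source channel with zero variance carries no transferable
contrast and is set flat to the reference mean. Normalization is
idempotent up to one intensity level of quantization.

**Binarization.** The methylene-blue density histogram of a smear field
has three populations: unstained background plus red cells (which take up
almost no basic dye), weakly basophilic leukocyte cytoplasm, and dense
nuclear chromatin. The default threshold is therefore a 3-class multi-Otsu
split keeping everything above the background class, which segments whole
cells; a plain 2-class Otsu (which lands between cytoplasm and chromatin
and yields nucleus-only masks) and a fixed threshold remain available.
Morphology: 3×3 binary opening, hole filling, and removal of components
below `min_area` (default 400 px at the generator's scale, roughly a third
of the smallest leukocyte's area). Components are 8-connected; boxes are
0-based and half-open, sorted by (y0, x0).

**Crops.** Each box is expanded by `pad_frac = 0.15` per side, clamped,
padded to square with the field's modal background color (no anisotropic
stretch), and resized to 224×224 — the classifier's input size, implied by
the architecture's first feature map (112×112 after a stride-2 pool).

**Quantization limit.** With continuous intensities, deconvolution inverts
the forward model to ~1e-15 (it is linear algebra). On 8-bit images the
recoverable density is floored by rounding: the OD error of one count is
about `0.5 / I`, so once total stain density exceeds ~2 (worst-channel
transmission below ~25/255) the concentration error necessarily exceeds
0.02 regardless of algorithm — measured worst case ~0.26 near density
(3, 3). Tests therefore assert the 0.02 bound on the resolvable domain
(total density ≤ 2.0, worst measured error ~0.015) and the 1e-6 bound on
the continuous domain up to 3.0 per stain.

## Stage 2 — compact channel-attention classifier (`compact_net`)

**Architecture.** Four convolution blocks, each
`maxpool3x3/2(relu(batchnorm(conv3x3(.))))`, with 64/128/256/256 output
channels and conv strides 1/1/2/1; a squeeze-and-excitation (SE) channel
attention module on the final 7×7×256 map; flatten (12544); FC 512 with
ReLU and dropout 0.5; FC 6 logits. Dropout regularizes the hidden FC
activations only — masking the six output logits at rate 0.5 injects
label-independent noise that measurably stalls from-scratch training
(validation accuracy 0.80 after five epochs with logit dropout versus
1.00 by epoch four without, under identical seeds), so descriptions that
place dropout "after each FC layer" are read as regularizing the FC
stage. The classifier head's weights are scaled to a tenth of their
Kaiming magnitude at init so training starts from near-uniform
probabilities (cross-entropy ≈ ln 6). Feature maps on a
224×224×3 input: 112×112×64 → 56×56×128 → 14×14×256 → 7×7×256. Trainable
parameters: 7,396,886 (7.397 M), counting conv biases and batch-norm
scale/shift — the accounting that reproduces the published size.
Multiply–accumulates for one input: 1.365 G (1.391 G counting elementwise
BN/ReLU/pool work); published rounded figures of "FLOPs" for such models
vary by convention within a few percent, so comparisons use a ±2 % band.

**SE gate.** Squeeze is global average pooling per channel; excitation is
a two-layer bottleneck (C → C/16 → C, ReLU inside). Published
descriptions of this attention block differ on the gate nonlinearity:
some print a softmax across channels, while the original design uses an
independent per-channel sigmoid. The two are not interchangeable in
practice — softmax weights sum to 1 over C = 256 channels, so the gated
feature map is attenuated by ~1/C on average, which measurably starves
the fully-connected head and slows from-scratch convergence by an order
of magnitude (in a matched comparison the sigmoid gate reached full
validation accuracy in two epochs where the softmax gate was still below
65 %). The default is therefore `se_gate="sigmoid"`; the softmax variant
remains available and both gates are gradient-checked and
property-tested (softmax weights form a probability vector per sample).
Removing the module changes the parameter count by exactly 8,464.

**Ablation variants.** `no_se`, `no_dropout`, `2_block`, `3_block`
(canonical prefix of channels/strides; the flatten width is re-derived
from the resulting feature-map geometry).

**Implementation.** The network is a small numpy framework written for
this package: im2col-lowered convolutions executed as single BLAS matrix
multiplies, with the im2col/col2im transforms and max-pooling expressed as
k×k strided-slice loops. Arrays are NHWC float32; the large im2col and
gradient buffers are persistent per layer so the training loop does not
thrash the allocator. Gradients of every layer are verified against
numeric differentiation in the test suite. Weight init is Kaiming-style
(paper-silent choice); the loss is softmax cross-entropy; dropout is
inverted (active only in training), so evaluation is bitwise
deterministic.

## Stage 2 training and evaluation (`train_eval`)

**Protocol.** Stratified 5-fold split (per-class fold counts within ±1);
five rounds rotate the roles: fold r tests, fold (r+1) mod 5 validates,
the remaining three train, so the five test folds are distinct and cover
the data exactly once.

**Optimization.** SGD with momentum 0.9, initial learning rate 5e-3
divided by 5 every 10 epochs (`lr(e) = 5e-3 / 5^floor(e/10)`), classical
momentum update `v ← μv + g`, `w ← w − lr·v`. Batch size defaults to 32
(8 in the smoke tests, trading BLAS efficiency for more SGD steps per
epoch on the small synthetic set). Model selection keeps the
best-validation-accuracy checkpoint, earliest epoch on ties; training can
stop early once a target validation accuracy is reached. Input
normalization (per-channel mean/std of training crops scaled to [0,1]) is
frozen into the checkpoint.

**Imbalance.** Published augmentation "to relieve imbalance" is
implemented as minority oversampling to the majority frequency, each
resample passing through random flips and right-angle rotations
(interpolation-free); both are configurable off.

**Metrics.** One-vs-rest TPR/TNR/FPR/FNR/Precision/Fβ (β = 1 by default)
from the 6×6 confusion matrix, plus support-weighted averages; ratios with
zero denominators are NaN and excluded from the weighting with a warning.
The weighted Fβ averages per-class Fβ values by support (this is the
averaging that reproduces the published weighted table from the published
confusion matrix). AUC is the normalized Mann–Whitney U of the class
score, identical to the trapezoidal area under the threshold-swept ROC.

**Model comparison.** Friedman rank test (mid-ranks for ties, chi-square
approximation with k−1 df — adequate at the small k, N used here) and the
post-hoc Nemenyi critical distance `CD = q_α(k) · sqrt(k(k+1)/(6N))` with
tabulated two-tailed infinite-df constants for k = 2…10 at α = 0.05/0.10
(q_{0.05,4} = 2.569 gives CD = 1.915 at N = 6).

## Stage 3 — risk and opinion (`diagnosis`)

Sanz/PETHEMA–GIMEMA stratification from the CBC: high if WBC > 10×10⁹/L,
otherwise low vs intermediate by platelets > 40×10⁹/L (both thresholds
inclusive on the printed side: WBC = 10 with platelets = 40 is
intermediate). A smear is morphologically suspicious when the classifier
reports at least `min_promyelocytes` promyelocytes (default 1 — any
circulating promyelocyte is abnormal). The advisory treatment strings are
"ATRA + arsenic" (low/intermediate) and "ATRA + arsenic + chemotherapy
induction" (high), always accompanied by a not-for-clinical-use
disclaimer. Patient-level per-cell ground truth is not modeled.

## Synthetic smears (`synthetic_smear`)

The generator renders fields through the same Beer–Lambert forward model
the focusing stage inverts. Defaults: 384×512 fields, 10 leukocytes and 60
red cells per field, uniform class mix, Gaussian sensor noise sd = 2
intensity counts, non-overlapping placement by rejection sampling (the
overlapping-cell failure mode of real dense smears is an explicit
non-goal; an `allow_overlap` flag exists only to demonstrate it). All
randomness flows from one seed through `SeedSequence` spawning; identical
recipes are bitwise reproducible.

Class signatures follow standard morphology: small lymphocytes with round
high-ratio nuclei; neutrophils with 3–5 nuclear lobes and pale pink
cytoplasm; large monocytes with kidney-shaped nuclei and gray-blue
cytoplasm; eosinophils with bilobed nuclei and coarse eosin granules;
basophils obscured by dense basophilic granules; large promyelocytes with
eccentric nuclei, heavy mixed granulation and a rod-shaped inclusion
motif. Cell sizes scale per class (lymphocytes smallest, promyelocytes
largest). Cytoplasm basophilia is kept above the background class of the
mb histogram for every class (0.26–0.45 density), as in real
Romanowsky-stained leukocytes, so whole cells — not just nuclei — survive
binarization.

**What passing tests show.** The synthetic classes are separable by
design (a standardized nearest-centroid baseline on simple color/texture
features reaches >80 %), so the learning smoke test demonstrates that the
architecture, gradients, optimizer and schedule work end to end — not that
the published accuracy transfers to real stains, scanners, or overlapping
cells. Reproduction of the published cross-validated accuracies would
require the original clinical/public image sets and is out of scope.

## Problem sizes in the test suite

The smoke training run uses the 600-crop synthetic dataset (100 per
class) under the fold protocol (360 train / 120 validation / 120 test),
batch 8, stopping when validation accuracy reaches 0.95 (within the
20-epoch budget). Focusing recall is measured on 20 default fields (200
planted leukocytes, IoU ≥ 0.5). Ablation variants are built at full input
size and trained one epoch on a 12-crop set to validate construction and
the training path. Unit tests run reduced-resolution twins (input 32–64)
of the same code paths.

## Known limitations

- No splitting of touching/overlapping cells; dense high-WBC smears will
  merge neighbors into one box.
- Stain vectors are defaults, not estimates from data, unless calibrated
  with `estimate_stain_vector`.
- The CPU implementation trains the full 7.4 M-parameter network at
  ~0.5 s/image; it is meant for verification and small studies, not
  GPU-scale experiments.
- The Friedman p-value uses the chi-square approximation; at very small N
  it is conservative.
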