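# Methods

This note records the modeling, numerical and design choices behind
`hctnet`, in the spirit of a methods appendix: what the procedure assumes,
which knobs matter, what the synthetic data does and does not emulate, and
where the design was genuinely open.

## Model

The classifier is a dual-branch hybrid over a shared convolutional stem.
The stem (LLFE) exists because patch tokenization straight from pixels makes
a transformer learn low-level structure (edges, layer boundaries) from
scratch — expensive on small clinical datasets — and because OCT B-scans
carry large uninformative background that max pooling suppresses. Its
residual dense blocks (RDB) follow the DenseNet idea: each of three
conv+LeakyReLU blocks receives the concatenation of the block input and all
earlier outputs. The concatenated channels are mapped back to the input
width by a 1×1 fusion convolution so the residual connection is
shape-compatible; a zero-parameter RDB is therefore the exact identity map,
which both the tests and the training dynamics (residual near-identity at
initialization) rely on.

The transformer branch is a standard pre-norm ViT encoder over the stem's
feature map. Attention scales per-head by `1/√d_head`; with a single head
this coincides with the `1/√D` scaling of the single-block formulation. The
class token's final layer-normalized state is the branch output. The
convolutional branch applies three RDB+pool stages to the same feature map
and reduces the final map by global average pooling followed by a pure
linear projection — average pooling keeps the parameter count independent of
input resolution, and the projection carries no nonlinearity because it only
aligns dimensions for fusion.

Fusion computes one linear score vector per branch, softmaxes across the
two branches per coordinate, and convexly combines the *original* branch
features (the linear maps produce weights only). Consequences used as
invariants: weights lie in [0,1] and sum to 1 across branches, and every
fused coordinate lies between the two branch values.

The loss is the standard multi-class cross-entropy (negative mean
log-likelihood of the true class). Softmax is always computed with the row
maximum subtracted; the loss floors probabilities at 1e-12 so a confidently
wrong prediction yields a large finite loss rather than an infinity.

## Autodiff engine

No deep-learning framework is a dependency: `hctnet._tensor` is a ~500-line
reverse-mode autodiff over float32 NumPy arrays providing exactly the
operations the model needs. Two numerical/engineering points matter:

- Convolution is evaluated as a sum of `k²` channel-mixing matmuls over
  shifted views rather than a materialized im2col matrix; on CPU the memory
  traffic of the column matrix, not the arithmetic, dominates. Max pooling
  resolves ties to the first element.
- After a backward pass the recorded graph is dismantled explicitly
  (parent links, closures and intermediate gradients dropped), so buffers
  are reclaimed by reference counting. Relying on Python's cycle collector
  lets hundreds of megabytes of activations accumulate between collections.

Gradients of every primitive are checked against central finite differences
(float32, tolerance 2e-2) in the test suite.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) with L2 weight decay 1e-4 added to the
gradient, batch size 32, learning rate `3e-4 · 0.1^⌊epoch/10⌋`, at most 50
epochs by default. Weights are Xavier-uniform; class and position tokens are
truncated-normal (std 0.02) because Xavier fan statistics are ill-defined
for single-row parameters. Early stopping monitors validation loss with
patience 10 and restores the best checkpoint. Normalization statistics
(mean/std) are computed on the training split only and frozen for
validation and test. Divergence (non-finite loss) aborts with the offending
epoch and batch recorded.

Splitting is at the patient level: patients are shuffled deterministically
from the seed and dealt into k folds; roles rotate over k repetitions.
Two schemes: `3:1:1` (k−2 folds train, one validates, one tests; k=5) for
small cohorts, and `one-train` (one fold trains; of the remainder, one fold
validates and the rest test; k=10) for large ones — the validation/test
proportion of the remainder is not dictated by the protocol and is fixed
here as one fold by index, configurable. Cross-fold aggregation is the
unweighted mean of per-repetition metrics; pooling confusion matrices first
is available behind a flag but is not the default, since averaging
per-repetition results is what the rotation protocol reports.

Ablation modes assemble nested sub-architectures: `vit_only` (raw-pixel
tokenization, no stem), `llfe_vit` (stem + transformer), 
`llfe_vit_cbranch_concat` (both branches, concatenation + FC instead of
adaptive fusion), and `full`.

## Evaluation metrics

Per class *i*, with one-vs-rest counts: accuracy `(TP+TN)/N`, sensitivity
`TP/(TP+FN)`, precision `TP/(TP+FP)`, as percentages. Overall: OA is micro
accuracy `trace(CM)/N`; OS and OP are unweighted macro means. A class with a
zero denominator (never predicted, or absent from the truth) produces a NaN
sentinel and is excluded from the macro mean with a warning — silently
substituting 0 or 100 would bias OS/OP. The paired t-test across fold
repetitions uses the exact Student-t closed form (via scipy); zero-variance
difference vectors return a degenerate flag instead of dividing by zero.

The noise harness adds i.i.d. zero-mean Gaussian noise in the original
intensity domain, clipped to the valid range ([0,1] float, [0,255] 8-bit;
the PSNR peak follows the same convention). Because clipping makes the
sigma→PSNR map nonanalytic, the sigma for a target mean PSNR (e.g.
26.91 dB) is found by bisection over a sample of images; PSNR is
`10·log₁₀(peak²/MSE)` with +∞ reported as a sentinel for identical images.

## Synthetic data

The generator emulates the *structure* of patient-grouped OCT classification
data, not OCT physics: 4–8 smooth bright bands (retinal layers) whose
count, depths, curvature and tilt are drawn per patient and shared across
that patient's scans (small per-scan jitter), multiplicative Rayleigh-like
speckle (OCT's characteristic texture — deliberately distinct from the
additive Gaussian perturbation used by the robustness harness), and
class-conditional lesions: dome bumps on a lower band (drusen/AMD), dark
intraretinal ellipses (DME), a bright irregular sub-band blob with band
disruption (CNV). Lesion strength and size scale together with the contrast
parameter. Intensities are floats in [0,1], serialized as 8-bit PNG.

Self-audits: a patient-disjoint nearest-centroid baseline on 8×8 block
means must score above chance but below perfect at default contrast, near
chance at zero contrast, and increase with contrast; intra-patient image
correlation must exceed inter-patient correlation (the reason splitting at
the patient level is the leakage-relevant unit). An image-level audit split
would be inflated by shared patient geometry — measurably so — which is
itself a demonstration of why the evaluation protocol splits by patient.

What passing tests on this data do **not** show: realistic speckle
statistics, anatomical layer counts, scanner variability, or the difficulty
of real lesion morphology; results on the phantom say the pipeline is
correct and the architecture trainable, not that clinical accuracy
transfers.

## Problem sizes and defaults

The full-size configuration mirrors ViT conventions: 224×224 inputs,
stem 32 channels, RDB growth 32, P=7 on the 56×56 stem output (N=64),
D=384, h=6, L=12, MLP width 4D; raw-pixel tokenization in `vit_only` uses
P=16 (N=196). The reduced configuration used by tests and the reproduction
script — 64×64 inputs, stem 16, growth 8, P=4 (N=16), D=128, h=4, L=4 —
was chosen as the smallest variant that retains every architectural
mechanism while training in minutes on one CPU core. Capability runs use a
200-image, 4-class phantom cohort (10 patients/class × 5 scans); the
ablation comparison trains 12 epochs per variant on a patient-level 3:1:1
split with validation-based checkpoint selection.

## Known limitations

- CPU-only float32 training; no dropout (none is used by the training
  recipe), no augmentation, no class-imbalance handling (deliberately
  excluded from the protocol).
- The RDB channel schedule (constant width, 1×1 fusion) is one reasonable
  resolution of an underdetermined design; serialized checkpoints depend on
  it and on the documented patch flattening order (row-major patches,
  row-major within patch, channels last).
- Bilinear resampling follows the Pillow half-pixel-center convention;
  other bilinear implementations differ at image borders, which changes
  pixel values slightly and is why the interpolation choice is pinned.
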