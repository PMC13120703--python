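# Methods

## Model

MedSpectralNet is a classification network for RGB (or grayscale-replicated)
medical images. A standard 18-layer residual backbone maps a B×3×H×W batch to
features `f_b ∈ R^{B×512×H/32×W/32}`. Two modules then process `f_b` in
parallel — they share no parameters and no sequential dependency, so either
can be evaluated first:

* **SpectralFlow (USM)** decomposes the map into frequency streams. A 1×1
  convolution halves the channel width (`x_l`, C/r channels, r = 2 by
  default). The global average-pooled descriptor of the *input* generates,
  through a learned 1×1 convolution and a softmax over the k² positions, one
  nonnegative k×k filter per reduced channel. Because the filters derive from
  a 1×1 descriptor they are spatially uniform: every non-overlapping k×k
  patch of `x_l` is replaced by the same filter-weighted mean, broadcast to
  the whole patch. This piecewise-constant map `x_la` is projected back to C
  channels (`x̃_la`) and the high-frequency residue is defined as
  `x_h = x − x̃_la`, which makes stream conservation a construction rather
  than an approximation. Per-stream channel attention (GAP → 1×1 conv per
  stream, normalized across the pair so `a_l + a_h = 1`) weights the two
  streams before a final 1×1 mixing convolution.
* **ContextGate (GM)** runs three pathways at matched width ⌊C/3⌋: spatial
  (depthwise 3×3 → internal SpectralFlow at full width → 1×1 reduction),
  gating (1×1 conv → GELU), and identity (1×1 conv). The gate is repeated
  once along channels to modulate the concatenation of the spatial and
  identity halves, a final 1×1 convolution restores C channels, and the input
  is added residually.

The pathway outputs are fused as `f_b + USM(f_b) + GM(f_b)`, refined by a
second, independently parameterized SpectralFlow, batch-normalized, globally
average-pooled and classified by a single linear layer. Softmax is applied
only when probabilities are requested.

## Why a built-in autodiff stack

The package implements its own compact reverse-mode autodiff engine and layer
library on numpy (`autograd.py`, `nn.py`): tensors with backward closures,
im2col-based (grouped) convolution whose forward and backward are single BLAS
matmuls, max pooling, batch norm composed from primitives, and the exact
GELU (`x·Φ(x)` via `erf`). This keeps the dependency surface to the
scientific-Python base stack and makes every gradient inspectable — Grad-CAM
reads activations and their gradients directly off the graph. All primitives
are verified against central finite differences in the test suite.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `patch_size k` | 3 | side of the non-overlapping smoothing patches; 5 is the coarser alternative |
| `reduction r` | 2 | low-frequency stream width C/r; halving is the standard bottleneck choice |
| `stream_norm` | `softmax_pair` | convex pair `a_l + a_h = 1`; `sigmoid` available for independent gates |
| `gate_nonlinearity` | `gelu` | smooth gate; `sigmoid` available when a strict (0,1) gate range is wanted |
| `branch_width` | ⌊C/3⌋ | C/3 is not an integer at C = 512; floor (170) with a 340→512 output projection |
| `zero_init_bias` | true | all 1×1 biases start at zero so zero-input→zero-output and the ContextGate identity hold exactly at init |
| optimizer | Adam, lr 1e-3 | no schedule, no weight decay; SGD (momentum 0.9) and RMSprop provided for ablations |
| benchmark epochs / batch | 200 / 128 | the full-scale protocol; desk-scale runs use far smaller values |
| CutMix | p = 0.5, α = 1 | box of area (1−λ)·H·W pasted from a shuffled partner; λ recomputed from the clipped box and used to mix the two cross-entropy terms |
| normalization | ImageNet mean/std | `(v/255 − mean_c)/std_c` per channel; grayscale inputs are replicated to 3 channels first |

Design points that were genuinely open and the choices made:

* **Gate vs. concatenation width.** The gate has ⌊C/3⌋ channels but modulates
  a 2⌊C/3⌋ concatenation; the gate is repeated once along channels so the same
  weights act on the spatial and identity halves — the least machinery that
  preserves the gate's shape.
* **Where the spatial path narrows.** Depthwise 3×3 and the SpectralFlow
  refinement run at full width C; the 1×1 reduction to ⌊C/3⌋ comes last, so
  the refinement sees the richest representation.
* **Non-divisible extents.** When k does not divide H or W the map is
  reflection-padded on the bottom/right to the next multiple of k and cropped
  after smoothing. An axis of length 1 (e.g. the 1×1 map a 32×32 input
  produces) cannot be reflected; edge replication is used there.
* **Fusion formula.** `f_b + USM(f_b) + GM(f_b)` — note GM carries its own
  internal residual, so `f_b` enters twice; the literal elementwise-addition
  reading is kept.
* **BN placement.** One 2-D batch-norm after the second SpectralFlow, before
  pooling.
* **GELU gate range.** GELU is unbounded above and slightly negative, so the
  gate is not confined to [0,1] under the default; the `sigmoid` mode
  guarantees that range when it matters.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` renders class-separable images as a smooth radial bump
(low-frequency shape: class-specific position and radius, jittered per
sample) plus a sinusoidal grating (high-frequency texture: class-specific
cycle count and orientation, random phase) with additive Gaussian noise
(σ = 0.05 on a [0,1] intensity scale by default). Class information is
deliberately split across the two frequency bands so that both SpectralFlow
streams carry signal; a band-energy oracle in the tests confirms the
high-frequency channel alone separates classes when noise is off. The
generator is byte-deterministic given its seed.

It does **not** emulate real medical data: no anatomy, no acquisition
physics, no inter-class morphological overlap, no label noise, and mild class
geometry. Passing the learnability test therefore demonstrates that the
architecture, losses, optimizers and pipeline are wired correctly and can fit
a two-band signal — not that benchmark-level accuracy on clinical images is
reproduced. Desk-scale problem sizes used throughout: 200 training / 100 test
images at 32×32 (backbone output 1×1×512), 12–30 epochs, batch 32 for the
smoke run (the 128 benchmark default would give only two updates per epoch at
this dataset size), and geometric augmentation disabled there to isolate
optimization behaviour.

## Numerical choices

* Float32 throughout the network; parameters use Kaiming-normal (fan-out)
  init, biases zero.
* Stream conservation `x̃_la + x_h = x` is exact in real arithmetic; verifying
  it in float32 re-adds the streams and can incur one rounding step, so tests
  assert to `2·eps32·max|stream|`. The pair identity `a_l + (1 − a_l) = 1`
  *is* exact in round-to-nearest and is asserted bitwise.
* The pairwise stream softmax is computed as `a_l = σ(ℓ_l − ℓ_h)`,
  `a_h = 1 − a_l` (algebraically identical to a two-way softmax, numerically
  stable, and exactly complementary).
* Batch norm uses ε = 1e-5, biased batch variance, momentum 0.1 running
  statistics (used in eval mode).
* Max pooling breaks ties by the first (row-major) maximal position.
* ROC sweeps collapse tied scores into one threshold step; the ROC area is
  trapezoidal over FPR and equals the concordant-pair probability with ties
  counted half. The PR area is the step-wise average-precision sum —
  trapezoidal PR interpolation is optimistically biased and deliberately not
  used. Multiclass curves are one-vs-rest on softmax columns; a class absent
  from the labels yields an undefined (flagged) curve excluded from the macro
  average.
* Grad-CAM: channel weights are spatial gradient means, the map is
  ReLU-rectified, bilinearly upsampled and min-max normalized; a raw map with
  maximum below 1e-8 is returned as all zeros with a `low_evidence` flag —
  activation failure is reported as an uncertainty signal, not an error.
* MAC convention: one multiply-accumulate per convolution/linear multiply-add
  (`C_out·C_in/groups·k²·H_out·W_out`, `C_in·C_out`); normalization,
  activations, pooling and elementwise arithmetic count zero, and 1 MAC is
  reported as 1 FLOP. This reproduces the standard published reference point
  of 11.7 M parameters / 1.81 G for a ResNet-18 with a 1000-class head at
  224×224 (profilers that also count pooling/norm land near 1.82 G).

## Complexity and profile

SpectralFlow's arithmetic is linear — affine — in the spatial area: the 1×1
convolutions on the feature maps scale with H·W while the filter-generator
and stream-attention convolutions act on the pooled 1×1 descriptor and are
resolution-independent, so equal area increments add exactly equal MACs (the
spatially dependent terms alone double when the area doubles). At 224×224 the
full model measures 18.3 M parameters and 1.92 G MACs, inside its 2.00 G
computational budget; the two SpectralFlow instances and the ContextGate all
operate on the 7×7 backbone map and together add less than 6 % of the
backbone's arithmetic.

## Known limitations

* CPU-bound numpy execution: fine for the desk-scale tests and small studies,
  not for 200-epoch benchmark training at 224×224.
* `backbone` supports the 18-layer residual layout only; pretrained weights
  can be loaded from a compatible state-dict archive but are never downloaded.
* The augmentation magnitudes (jitter ranges, blur σ, perspective scale,
  erase fraction) are common mild defaults, all exposed in
  `AugmentationConfig`, since no canonical values exist for them.
* Grad-CAM sites are the post-depthwise ContextGate activation and the second
  SpectralFlow output; other tensors can be registered by extending
  `MedSpectralNet.ACTIVATION_SITES` and the `activations` dict.
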