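# Methods

## The model

`binet` implements a hierarchical windowed-attention classifier for B-mode
liver ultrasound, organized after the ventral visual pathway
(V1 → V2 → V4 → IT), together with the two biologically motivated additions
that distinguish it from a plain hierarchical vision transformer: a
center–surround inhibition module in the first stage and top-down feedback
from the high stages into the first.

**Dataflow.** For an input image `I` (3 channels, side divisible by 32):

```
F0 = PE(I)                                 patch embedding (4×4 patches)
F1 = DS(PA(F0) + RFFE(F0))                 stage 1 (V1)
F2 = DS(PA(F1))                            stage 2 (V2)
F3 = DS(PA(F2));  F4 = PA(F3)              stage 3 (V4)
l  = CB(F4)                                classification (IT): 2 logits
```

`PE = LN(Flatten(Conv2D(I)))` maps non-overlapping 4×4 patches to 96
channels (2·C·4·4 with C = 3). `DS = Linear(LN(Cat(·)))` concatenates 2×2
token neighborhoods and projects 4c → 2c channels, halving resolution.
`CB = Linear(GlobalAvgPool(LN(·)))`.

**Parallel attention (PA) block.** Both attention flavors read the *same*
input and are fused by addition:

```
F'    = MLP(LN(W(LN(F)) + F)) + (W(LN(F)) + F)      W  = window attention
F''   = MLP(LN(S(LN(F)) + F)) + (S(LN(F)) + F)      S  = shifted-window attention
F_out = F' + F''
```

Each path owns its normalization, attention and MLP parameters, so ablation
variants that drop one path are well defined (`binet_wo_swmsa`,
`binet_wo_wmsa`) alongside the conventional alternating scheme
(`serial_baseline`, W then S in sequence).

**Window attention.** Tokens are partitioned into non-overlapping S×S
windows and each window runs multi-head attention
`softmax(QKᵀ/√d + b)V`, with Q, K, V produced by bias-free linear maps and
`b` a learnable relative-position bias indexed by the (Δrow, Δcol) offset
within the window (one table per layer, per head). The shifted variant rolls
the grid cyclically by ⌊S/2⌋ before partitioning so information crosses
window borders; token pairs that the roll wrapped around from opposite sides
of the image are excluded with an additive −10⁹ mask. Grids not divisible by
S are zero-padded right/bottom, padded tokens are masked out as attention
keys, and the output is cropped back.

**Center–surround inhibition (RFFE).** V1 neurons are suppressed when their
non-classical surround (nCRF) is stimulated together with the classical
receptive field (CRF). The classical model is a difference of Gaussians with
surround scale 2σ:

```
DoG_σ(x,y) = N(0, (2σ)²)(x,y) − N(0, σ²)(x,y)
```

Here the suppression is realized with trainable depthwise convolutions on
the stage-1 token grid:

```
nCRF = C5×5(C5×5(x)) − C3×3(C3×3(x));   CRF = C3×3(x);   Out = CRF − nCRF
```

followed by a 1×1 channel mix. All convolutions are bias-free, zero-padded
'same', and purely linear (no activation or normalization). Kernels are
initialized from a *zero-sum* discrete DoG (each sampled Gaussian normalized
to unit sum on the truncated grid before differencing, σ = 1); raw truncated
samples of the continuous DoG at 3×3/5×5 lose most of the σ = 2 surround
mass and would respond strongly to constant inputs, defeating the purpose of
surround suppression. The analytic `dog_weight`/`discretize_dog` functions
keep the pure closed form for reference and testing.

**Feedback.** The first-stage representation receives upsampled high-stage
features: `F0 ← PE(I) + US(F2) + US(F3) + US(F4)`. The definition is
circular (F2…F4 are computed from F0), so it is unrolled: pass 1 is purely
feed-forward; each subsequent pass adds feedback computed from the previous
pass (`feedback_passes`, default 1). Every feedback connection is a fixed
bilinear resampling to the F0 grid followed by a 1×1 linear projection that
is **zero-initialized**, so the untrained network is exactly feed-forward
and feedback is a learned refinement. By default gradients are truncated at
the feedback inputs (`detach_feedback=True`): the previous pass's features
are treated as constants, which halves the training cost of a pass while the
projections themselves still receive full gradient (their input is a
constant; their output is on the differentiated path). Set it to `False`
to backpropagate through the whole unrolled iteration.

## Numerical core

No deep-learning framework is used: the package carries its own
reverse-mode automatic differentiation over NumPy arrays
(`binet.autodiff`), with exactly the operations the network needs (batched
matmul, softmax with additive masks, erf-based GELU, depthwise convolution
as K² shifted multiply-adds, cyclic roll, pad/crop, gather for the bias
tables, bilinear resampling expressed as two fixed interpolation matrices).
Every operation's backward pass is tested against central finite
differences, and the whole attention stack against brute-force dense
attention oracles. Computation is float32 by default; feeding float64
arrays runs the tape in double precision (used by the oracle tests).

## Architectural parameters

| parameter | full scale | desk scale | rationale |
|---|---|---|---|
| input size (px) | 224 | 128 | clinical protocol / CPU budget |
| patch size | 4 | 4 | embedding 2·C·4·4 = 96 at C = 3 |
| stage channels | 96/192/384/768 | 24/48/96/192 | doubling per merge |
| heads per stage | 3/6/12/24 | 3/6/12/24 | keeps head_dim constant (32 / 8) |
| window size S | 7 | 4 | divides the 56/28/14/7 (32/16/8/4) grids |
| MLP expansion | 4 | 4 | backbone convention |
| LN ε | 1e−5 | 1e−5 | convention |
| stage depths | 1/1/2 PA blocks | same | one PA per stage plus the F4 block |
| feedback passes | 1 | 1 | one refinement pass |

Inputs are standardized (x − 0.5)/0.5 from the [0,1] pixel range inside the
forward pass. This is not cosmetic: `PE = LN(…)` with zero-initialized
biases is exactly invariant to per-patch brightness scaling
(LN(a·x) = LN(x) for a > 0), so without a fixed shift the echogenicity cue
— the main diagnostic signal — would be erased at the first layer and would
have to be re-learned slowly through bias drift. The fixed shift makes
patch brightness rotate the token direction instead, which survives
normalization. It is also what the usual vision-transformer preprocessing
does.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e−8) with the L2 term added to the gradient,
global learning rate 1e−4, weight decay 5e−2, cross-entropy over the two
logits, 10 epochs by default. No learning-rate schedule, no dropout, no
stochastic depth: the forward pass is deterministic, and a fixed seed
reproduces the run bitwise (initialization, validation carve-out and batch
order all derive from it). 25% of the train/validation pool is carved out
as a stratified validation set; the best-validation checkpoint is kept
alongside the final weights. Batch size defaults to 8. An optional hook
copies shape-matching arrays from a user-supplied `name → array` archive
for transfer-learning experiments; nothing in the package depends on
external weights.

## The phantom generator

The generator emulates the two sonographic appearances the classifier must
separate, not ultrasound physics. Each image (720×480, 8-bit, 3 identical
channels) is

```
image = brightness · exp(−attenuation · depth) · (1 − contrast · vessels) · speckle
```

with class-conditional parameter draws chosen once to mimic the reported
appearance of moderately severe steatosis versus normal liver:

| parameter | normal | fatty | emulates |
|---|---|---|---|
| base echogenicity | U(0.30, 0.45) | U(0.60, 0.80) | "bright liver" |
| attenuation slope (per depth) | U(0, 0.10) | U(0.30, 0.70) | far-field darkening |
| vessel wall blur σ (px) | U(0.5, 1.5) | U(4, 8) | blurred vessel walls |
| vessel contrast | U(0.35, 0.55) | U(0.08, 0.20) | vessel conspicuity |
| vessels per image | 3–6 | 3–6 | portal/hepatic branches |
| speckle scale | U(0.5, 0.9) | U(0.5, 0.9) | class-independent noise |

Vessels are smoothed random walks of random thickness; speckle is the
squared magnitude of a complex Gaussian field smoothed with σ = 1.2 px
(exponential intensity statistics with local correlation — a first-order
surrogate for fully developed B-mode speckle), normalized to mean one and
applied multiplicatively. Everything is deterministic given the per-image
seed recorded in the dataset manifest.

Datasets are split 4:1 into train/validation versus test *per class before
augmentation*; augmentation (rotations 30°/75°/135°/225° with reflect
padding, isotropic scale in [0.8, 1.2], horizontal/vertical flips) is
applied only to the train/validation pool, so no derivative of a test image
can leak into training. Rotations that are multiples of 90° are exact
(array rotation); others use bilinear resampling.

**What passing tests do and do not show.** The phantoms are strongly
separable by design (a mean-intensity threshold alone exceeds 90% on
default parameters, mirroring how conspicuous moderately severe steatosis
is to a radiologist), so the desk-scale experiment demonstrates that the
architecture, gradients and training loop work end to end — it says nothing
about clinical accuracy. Real ultrasound has probe-dependent speckle
statistics, acoustic shadowing, the liver–kidney interface used in clinical
grading, operator variability and rare confounders, none of which are
modelled.

## Problem sizes used in the shipped experiments

The desk-scale experiment (tests and `scripts/acceptance.py`) uses a
100-normal + 150-fatty dataset (200 train/validation, 50 test), the desk
network (≈1.3 M parameters), batch 8 and 4 epochs — convergence on these
phantoms is reached by epoch 2–3, so the shorter schedule is used; the
protocol allows up to 10.

## Degenerate inputs and edge cases

Zero-denominator metrics (empty positive or negative class, precision with
no positive predictions) return 0 with a logged warning rather than NaN.
Non-finite activations raise an error naming the stage. Grids not divisible
by the window size are padded and masked as described; grids smaller than a
convolution kernel, odd-sized grids at a merge, and infeasible split ratios
raise explicit errors. With `speckle_scale = 0`, no vessels and no
attenuation the phantom degenerates to a constant image, which exercises
the zero-variance branch of layer normalization (output = β).

## Known limitations

- CPU-only NumPy execution: the full-scale 224-px configuration runs
  (≈2 s/image forward) but is impractical to train from scratch here; the
  desk preset is the supported training scale.
- The feedback unrolling and its gradient truncation are one reading of a
  circular definition; alternatives (joint fixed-point solving, full
  backpropagation through passes) are configurable only in part
  (`detach_feedback=False`).
- The relative-position bias is per-head and per-layer; no cross-layer
  sharing.
- Binary classification only; no severity grading, no ROC/AUC analysis.
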