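# Methods

## Problem and model

The package segments a single plant leaf from an RGB field photograph as a
binary per-pixel labelling (foreground leaf = 1, background = 0). The model is
a hybrid CNN/transformer encoder–decoder with three interacting parts:

**Multi-scale branch (MSFF).** A five-stage U-shaped encoder–decoder. Each
encoder stage is a *Swin-Trans-Conv* block: a 1×1 convolution maps the input
to the stage's working channel count C, the channels are split into two equal
halves, one half passes through a depth-2 Swin-transformer stage (a windowed
multi-head self-attention block followed by a shifted-window block, each with
a pre-norm residual MLP), the other half through a residual double 3×3
convolution (out = Conv(ReLU(Conv(x))) + Conv(x), residual on the first
conv's output). The halves are concatenated, fused by a 1×1 convolution, and
added to the block input (via a 1×1 projection when the channel count
changes). Stages are separated by 2×2 average pooling; channels follow
base·(1, 2, 4, 8, 16) — 32/64/128/256/512 at the default width. The decoder
mirrors the encoder with kernel-2 stride-2 transposed convolutions, U-Net
style skip concatenation, and a Conv–BatchNorm–ReLU per level.

**Full-scale branch (FSFF).** Encoder stages 2–5 are compressed to the base
channel count with 1×1 convolutions, upsampled (nearest-neighbour, ×2 per
stage of depth) to full resolution, summed, and added to the stage-1 feature.
The fused map then passes through four sequential Conv–BN–ReLU blocks at base
channels and full resolution, preserving boundary detail the pooling pyramid
destroys. The deepest of the five fused features is the bottleneck (encoder
stage 5) — the feature the decoder starts from; the stage-1 feature serves as
the residual of the fusion sum.

**Bidirectional attention gates (BAF).** At each of the four decoder levels a
pair of gates exchanges information between the branches. The multi-scale
gate (MSFG) pools the full-scale feature down to the decoder resolution,
concatenates, compresses back to the decoder channel count (1×1 conv),
projects to one channel, and applies a sigmoid; the resulting spatial map
α ∈ [0,1] rescales the compressed feature, which feeds the next decoder
level. The full-scale gate (FSFG) compresses the decoder feature to base
channels, upsamples, adds it pixel-wise to the full-scale feature, fuses with
a 3×3 convolution, and gates with its own sigmoid map; the result feeds the
next full-scale block. The prediction head is a 1×1 convolution plus sigmoid
on the final full-scale feature (the full-resolution stream carries the
boundary detail, so it hosts the head). The fourth MSFG's output has no
consumer — there is no fifth decoder level — but the gate is kept so each
level carries the full bidirectional pair; its parameters receive no
gradient.

Ablation variants nest strictly: the baseline (SU-Net) is a half-width U-Net
whose encoder stages are single Conv–BN–ReLU layers; +MSFF replaces each
encoder layer with the Swin-Trans-Conv block; +FSFF adds the full-scale
branch; +BAF adds the gates. Parameter counts strictly increase in this
order, while the *split* hybrid block stays cheaper than an unsplit full-C
Swin stage plus full-C residual convolution — both properties are asserted in
the tests.

## Shifted-window attention details

Tokens are the spatial positions of the feature map (patch size 1 — the map
entering a stage is already downsampled, so further patchification would
discard resolution for no benefit). Window size defaults to 8 with shift 4,
dividing every stage resolution derived from 512. Heads are sized at 16
channels per head with a floor of one head. A learned relative-position bias
(one table per head over in-window offsets, truncated-normal initialised) is
added to the logits; it can be switched off, which the oracle tests do.
Shifted blocks cyclically roll the map by (−shift, −shift), attend within
windows under an additive mask (−1e9 on pairs whose tokens were not
contiguous before the roll, which underflows to exactly zero weight after
softmax), and roll back. Maps not divisible by the window are reflect-padded
and cropped after the block. Maps smaller than the window fall back to a
single whole-map window without shift (reflect padding cannot exceed the map
size, and a shift is meaningless when one window sees everything); this
engages at the two deepest stages of 64×64 inputs.

Correctness is established against a brute-force oracle that computes dense
softmax(QKᵀ/√d)V over *all* tokens of the map with an explicit allowed-pair
membership matrix, sharing no code with the windowed path; the two agree to
1e-5 (in practice machine epsilon in float64) on 8×8–16×16 maps, shifted and
unshifted.

## Loss

L_total = α·L_bce + (1−α)·L_iou with α = 0.5. L_bce is the per-pixel binary
cross-entropy, reduced by mean (default) so the α = 0.5 balance is resolution
independent; a sum reduction is available. L_iou = −log of the soft Jaccard
ratio Σ(g·p)/Σ(g+p−g·p) over all pixels of the batch (one ratio per batch,
not per image). Probabilities are clamped to [ε, 1−ε] with ε = 1e−7 before
logarithms. An all-empty prediction against an all-empty target is defined as
zero loss with a warning. Closed forms used as anchors: p ≡ 0.5 gives
L_bce = ln 2; p ≡ 0.5 against a half-foreground mask gives L_iou = ln 3; their
α = 0.5 mix is ≈ 0.8959.

## Evaluation indices

From pixel tallies TP/TN/FP/FN: accuracy PA, recall PR = TP/(TP+FN),
precision PP = TP/(TP+FP), specificity PS = TN/(TN+FP), IoU = TP/(TP+FP+FN),
F1 = 2·PR·PP/(PR+PP). Probability maps are thresholded at 0.5 before
counting. Degenerate denominators follow the empty-set convention: the index
is 1 when the counterpart error set is also empty, else 0. Dataset scores are
per-image means (mIoU convention); pooled-count aggregation is exposed as an
alternative. Tables print on the 0–100% scale with two decimals.

## Training protocol

SGD with initial learning rate 0.01 and batch size 4; the reference schedule
is 60 epochs of 350 batches. Momentum 0.9, zero weight decay and a constant
learning rate are this package's documented defaults where the protocol is
otherwise silent. An "epoch" is iters_per_epoch batches resampled from the
training split, so small synthetic datasets still define one. Model selection
keeps the best validation mIoU. Convolutions are He-normal initialised,
attention projections truncated-normal (σ = 0.02); every random draw flows
from one integer seed, and CPU runs are bit-reproducible.

The numerical core is a small reverse-mode autodiff engine over NumPy
(`bafnet.nn`): broadcast arithmetic, batched matmul, stride-1 convolution by
im2col, kernel-2 stride-2 transposed convolution, non-overlapping average
pooling, nearest upsampling, reflect/zero padding, gathers for the bias
tables, and the usual nonlinearities. Every primitive is verified against
central-difference numeric gradients. Activations and parameters are float32;
the oracle tests cast to float64. An inference mode (`no_grad`) skips tape
recording so large forward intermediates are freed eagerly — a full-width
512×512 forward pass runs in ≈1 GB.

## Synthetic data

The generator emulates the structure of single-leaf field photographs: a
star-convex leaf r(θ) = r₀(1 + a·sin(kθ + φ)) (defaults: r₀ = 0.30 of the
image side, k = 5 lobes, a = 0.08) with centre jitter of 5%, an HSV-green
textured body with radiating darker veins, Poisson-distributed brown
elliptical disease spots (mean 6 per leaf; 0 for healthy-leaf fixtures), over
a plain, cluttered (soft colour blobs) or soil-like background, with an
optional linear illumination gradient of ±25%. The star-convex
parameterisation guarantees a simple region with analytic area
πr₀²(1 + a²/2), which the tests check to 2%. The defaults are meant as a
plausible desk-scale stand-in for cluttered field imagery; the generator does
*not* reproduce real leaf intensity statistics, occlusion, multiple leaves,
or camera noise — so passing tests demonstrate that the architecture,
optimisation and bookkeeping work, not field-grade accuracy.

## Problem sizes used in the checks

The oracle comparisons run on 8×8–16×16 maps; the architecture contract runs
one full-width (base 32) forward at 512×512; the trainability check fits the
full model at base 8 on eight 64×64 synthetic leaves for 200 SGD steps
(batch 4, lr 0.01), requiring the loss to at least halve and the training
mIoU to reach 0.95 — it typically reaches ≈0.99 with the loss falling two
orders of magnitude. These sizes were chosen as the package's own desk-scale
reference points; wider models and longer schedules scale the same code.

## Known limitations

- Single-class (leaf/background) segmentation only; no instance separation
  or leaf counting.
- CPU-only NumPy execution: full-resolution training at published scale is
  out of reach; the package targets correctness and desk-scale study.
- The LabelMe reader consumes polygon shapes only; other shape types are
  skipped.
- Self-intersecting annotation polygons are filled by the even-odd rule with
  a warning rather than rejected.
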