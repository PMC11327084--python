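# Methods

## The network

BFNet is a U-shaped encoder–decoder for binary lesion segmentation whose
distinguishing feature is a single fused **mid layer** built from *all*
encoder scales, consumed by *every* decoder stage, with **global-context
(GC) attention** after each encoder, mid, and decoder stage.

### Encoder

Stage `i` (of 3–5) runs at resolution `S / 2^(i-1)` with `w · 2^(i-1)`
channels (`S` = input size, default 512; `w` = base width, default 64).
Stage 1 applies two 3×3 conv→batch-norm→ReLU blocks and attention without
changing resolution; every deeper stage first halves resolution with a 3×3
stride-2 convolution that doubles the channels — the downsampling itself is
learned, and no pooling operator appears anywhere in the network — then
applies the two conv blocks and attention. Stage 1 must preserve
resolution: it is the only schedule under which the mid layer's part
assignment (two stages downsampled, one unchanged, two upsampled) and the
maximum resampling step of 4 are simultaneously satisfiable.

### Global-context attention

A full non-local block computes, for every query position, an attention-
weighted aggregate over all positions. Empirically the aggregate is nearly
query-independent, which licenses computing it **once** per map:

    pool(x) = Σ_j softmax_j(w_kᵀ x_j) · x_j            (one C-vector per map)
    GCA(x)  = x + W_up · relu( LN( W_down · pool(x) ) )

`W_down : C → ⌊C/8⌋` and `W_up : ⌊C/8⌋ → C` form a squeeze-excitation-style
bottleneck with compression ratio 8; `LN` is layer normalisation over the
bottleneck channels. Two structural consequences are tested directly: the
added term is constant over spatial positions within each channel, and
zeroing `W_up` makes the block the identity. A brute-force non-local
implementation (`nonlocal_oracle`) exists purely as a test oracle,
including a demonstration that its per-query contexts are nearly equal on
small inputs.

Degenerate-width guard: for `C < 8` the bottleneck width floors at 1, and
layer norm over a single channel would map every value to β, silencing the
context pathway and blocking its gradients. A single-channel `LN` therefore
applies only its affine part. The parameter count of one block is exactly
`C+1 + 2·C·⌊C/8⌋ + 2·⌊C/8⌋` (context projection with bias, two bias-free
projections, norm affine), asserted in tests.

### Mid layer

Every encoder output is brought to the reference resolution — the middle
stage's, `(depth+1)//2`, so no resampling factor exceeds 4 (larger factors
visibly destroy detail) — unified to a common branch width (`4·w`, i.e. 256
at default width, chosen so the five branches concatenate to exactly 1280
channels), and attended. Shallower stages are downsampled by stride-2
convolutions (compressing real content); deeper stages are upsampled by 4×4
transposed convolutions, the only place content must be synthesised.
The concatenation (1280 channels by default) is reduced to a quarter (320)
by a 3×3 convolution unless the high-dimensional ablation (`reduce=False`)
is selected, passed through two further 3×3 conv blocks, and attended.
Fusion by **concatenation** rather than elementwise addition is forced by
the channel arithmetic: only concatenating five 256-channel branches
produces 1280.

### Decoder

Stage `i` concatenates (a) the next-deeper decoder output upsampled ×2 with
a 4×4 transposed convolution (a 4-kernel always lands on an even size, so
nothing is cropped or padded away), (b) the mid layer resampled to stage
resolution (stride-2 convs down / 4×4 transposed convs up, factor ≤ 4), and
(c) the same-stage encoder output; a 1×1 convolution cuts the concatenated
width to ⌈W/4⌉, then batch-norm, ReLU, and attention. The deepest stage
omits (a). A 1×1 head plus logistic map yields per-pixel foreground
probabilities at exactly the input resolution; this shape law is tested for
depths {3,4,5} × sizes {64,128,512}.

## Loss and metrics

Training minimises the soft Dice loss over all N pixels,

    L = 1 − (2 Σ pᵢtᵢ + ε) / (Σ pᵢ² + Σ tᵢ² + ε),   ε = 1e-6,

where ε guards the 0/0 of an empty mask and keeps `L ∈ [0,1]`. Evaluation
binarises probabilities at 0.5 (the threshold is a package choice; nothing
in the procedure pins it) and computes per-image confusion counts; IoU,
pixel accuracy (recall) and precision are averaged **unweighted over the
background and foreground classes** for the m-prefixed variants — under
the small-lesion regime this places mIoU above the foreground Dice, the
ordering observed in practice for this family of metrics. A class absent
from both prediction and truth scores 1 for that image; absent from only
one side scores 0.

Validation aggregates per-image scores by the **grouped mean**: scores are
partitioned in order into groups of ten, each group is averaged, and the
group means are averaged, damping single-image outliers. A partial final
group is kept as its own group (the procedure is otherwise silent on
remainders). The per-image CSV dump allows the grouped mean to be
recomputed exactly (tested to 1e-9).

Confusion overlays colour true positives purple, false negatives yellow,
false positives green over the grayscale image.

## Training recipe

Adam (first-moment decay 0.9 — "momentum" in the optimizer's vocabulary —
β₂ = 0.999) with the learning rate cosine-annealed per epoch from 1e-4 to
1e-7 (endpoints exact, monotone non-increasing), batch size 4, seed 2024,
flip (p = 0.5 each axis) and ±15° rotation augmentation with per-image
intensity rescaling to [0,1]. Epoch count is corpus-dependent and
config-exposed; phantom-scale runs use 30 (of an allowed ≤ 50) epochs,
which is past the point of diminishing returns on this corpus. Runs are
bit-reproducible for a fixed seed: weight initialisation, shuffling and
augmentation all derive from it, and all computation is single-threaded
numpy. Divergence (non-finite loss) aborts with a diagnostic rather than
continuing silently.

## Numerical core

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine on numpy (`bfnet.autodiff`) providing exactly
the operator set the network needs — broadcast arithmetic, reductions,
batched matmul, softmax, im2col convolution, strided transposed convolution
— with hand-written convolution gradients verified against central
differences (in float64) and against `scipy.signal.correlate2d`; the
transposed convolution is additionally checked to be the exact adjoint of
the convolution. Forward/backward arithmetic is float32; Adam moments are
float64 for accumulation stability.

## Synthetic phantoms

The generator emulates the gross appearance of axial chest CT with small
bright lesions: smooth textured dark background (≈0.15 on [0,1]), two
elliptical lung fields (≈0.40), and 1–3 bright lesions (contrast +0.45)
whose supports are rotated ellipses (axis ratio 0.6–1) with low-order
harmonic boundary perturbation (wobble 0.25) — irregular boundaries are
the behaviour of interest, and pure discs would be trivially easy. Lesion
centres are sampled inside a lung field with a margin of one radius.
Gaussian pixel noise (σ = 0.03) is added last; the mask is the exact
analytic union of lesion supports, so labels are perfect by construction.
Defaults: 64px images, radius 3–7 px, giving foreground fractions of
roughly 0.5–8% per image (analytically bounded and tested).

What the phantoms do **not** model: projection/reconstruction physics,
Hounsfield calibration, anatomy beyond two ellipses, ambiguous or noisy
labels, inter-scanner variation. Passing the held-out criterion therefore
demonstrates that the architecture, loss, optimiser and pipeline are wired
correctly and can learn irregular small-structure boundaries from realistic
class imbalance — not clinical-grade performance on real CT.

## Problem sizes

Phantom-scale runs use a depth-3, base-width-8 network on 64px images
(200 phantoms, 180/20 split) — the same architecture family as the default
5-stage width-64 512px configuration, scaled to what a single CPU trains in
minutes. Structural constants (1280-channel concatenation, 4× reduction,
compression ratio 8, resampling bound 4) are asserted on the default
configuration itself.

## Known limitations

- Batch-norm statistics make the loss depend on batch composition; with
  batch 1 (single-sample overfit) the spatial statistics still stabilise it.
- The im2col convolution materialises patch matrices; memory grows with
  batch × resolution × channels × 9. Fine at the sizes used here; a tiled
  implementation would be needed for large batches at 512px.
- Multi-class segmentation is out of scope; the head is binary.
- The high-dimensional (no-reduction) variant is supported but slow at
  full size, as its widths are 4× larger through the mid layer and decoder.
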