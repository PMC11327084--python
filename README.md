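# bfnet

Binary medical-image segmentation with a **full-encoder fused mid layer**:
a U-shaped convolutional network in which every decoder stage sees, in
addition to its usual same-level encoder skip, a single "mid" feature map
fused from *all* encoder scales — so shallow decoder stages receive deep
positional semantics and deep stages receive shallow boundary detail —
with lightweight global-context attention after every stage. The target
application is small-lesion CT segmentation (e.g. pulmonary embolism),
where lesions occupy a tiny fraction of the image and boundary accuracy
dominates the score.

The package provides the network, the Dice-loss training loop, the
segmentation metric suite, and a seeded generator of CT-like lesion
phantoms with exact masks, so the complete train/evaluate pipeline runs
self-contained on one CPU. The numerical core is a small built-in
reverse-mode autodiff engine on numpy (see `docs/methods.md`).

## The model in brief

Encoder stage `i ∈ 1..d` (depth `d ∈ {3,4,5}`) runs at resolution
`S/2^(i-1)` with `w·2^(i-1)` channels; downsampling is a learned 3×3
stride-2 convolution (no pooling). Every stage output `X_En^i` is resampled
(factor ≤ 4) to the middle stage's resolution, unified to width `4w`, and
concatenated into the mid layer

    X_mid = GCA( C( C( reduce( concat_i  branch(X_En^i) ) ) ) ),

1280 → 320 channels at the default `d=5, w=64`. Decoder stage `i` then fuses

    X_De^i = GCA( ReLU( BN( 1×1-conv[ up(X_De^(i+1)) ⧺ resample(X_mid) ⧺ X_En^i ] ) ) ),

cutting the concatenation to a quarter of its width; upsampling uses 4×4
transposed convolutions. `GCA(x) = x + W_up relu(LN(W_down pool(x)))` adds a
softmax-pooled global context vector (compression ratio 8) identically at
every position. Training minimises the soft Dice loss
`1 − (2Σpt + ε)/(Σp² + Σt² + ε)` with Adam and a cosine learning-rate
schedule (1e-4 → 1e-7); validation reports Dice, mIoU, mPA and mPrecision
aggregated as means of group-of-ten means.

## Worked example

Generate a phantom corpus, train a small variant, evaluate, and predict:

```sh
bfnet synth --out corpus --n 200 --size 64 --seed 2024
bfnet train --data corpus/manifest.csv --out run \
    --depth 3 --base-width 8 --size 64 --epochs 30 --seed 2024
bfnet eval --checkpoint run/checkpoint.npz --data corpus/manifest.csv \
    --out run/eval --overlays
```

The training command prints

```
final train loss 0.0688
best val dice 0.9509
```

and `eval` writes `metrics.json` / `per_image_metrics.csv` plus
purple/yellow/green (TP/FN/FP) overlay PNGs, printing

```json
{
  "dice": 0.95092918482731,
  "miou": 95.17526658781537,
  "mpa": 97.59227204994161,
  "mprecision": 97.37491862807542
}
```

Read: on the 20 held-out phantoms the model overlaps ~95% of lesion pixels
(Dice, grouped mean); mIoU/mPA/mPrecision average the per-class scores over
background and foreground, so they sit near 100% for the dominant
background and are pulled down by foreground errors. An untrained network
scores Dice 0.0 on the same split. `bfnet predict --checkpoint
run/checkpoint.npz --image corpus/images/phantom_0000.png --out mask.png`
writes a binary mask at the input resolution (here 216 foreground pixels).

The library mirrors the CLI: `generate(PhantomSpec(...))`,
`train(ModelConfig(...), TrainConfig(...), samples)`, `evaluate(model,
samples)`, `model.segment(image)`.

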