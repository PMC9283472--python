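# Methods

This note documents the model, the synthetic data, and every numerical
decision a maintainer would need to reproduce or modify the package's
behavior. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Problem and pipeline

Percent mammographic density (PD) is the areal fraction of fibroglandular
("dense") tissue within the breast, `PD = 100·Σŷ_d / Σŷ_b`, computed from
two binary masks. Estimating it automatically requires two segmentations
with different failure modes: the breast area (hard in MLO views, where the
pectoral muscle has dense-tissue-like intensity and must be excluded) and
the dense tissue within it. The package couples the two as a multitask
problem: a shared encoder, two task-specific decoders, trained jointly.
Dense-tissue segmentation is treated as the main task; breast-area
segmentation is the auxiliary task that teaches the encoder where the
breast ends.

At inference, each head emits per-pixel two-class probabilities; the
region-of-interest probability is thresholded at 0.5 (ties count as
foreground, making the rule deterministic), masks are restored to the
native image resolution by nearest neighbor, and PD is derived from raw
pixel counts.

## Architecture

`NetworkConfig` defaults: 1 input channel, 256×256 input, depth 4 (2×
down-samplings), base width 64 with channel doubling per stage, bottleneck
dilations (1, 3, 5), block dilations (1, 3), batch normalization, two
two-class softmax heads. Tests and the desk-scale studies use width 8 and
depth 2 at 64×64, which preserves every structural property at a fraction
of the cost.

* **Multilevel dilated residual (MDR) block.** The original publication of
  this block does not print its internal wiring, so the package adopts an
  explicit, documented interpretation: per configured dilation rate, a
  normalization → ReLU → 3×3 dilated convolution branch; branches are
  concatenated and fused by a 1×1 convolution; an identity shortcut (1×1
  projection when channel counts differ) is added. Padding equals the
  dilation rate, so spatial size is always preserved. With all convolution
  weights zeroed the block reduces exactly to its shortcut — the property
  the tests pin down.
* **Bottleneck.** Three parallel dilated 3×3 convolutions (rates 1, 3, 5)
  over the deepest encoder features, concatenated and fused by a 1×1
  convolution. Merging by concatenation + fusion (rather than summation)
  was chosen for expressiveness; the rates are configurable.
* **Decoders.** Per stage: stride-2, kernel-2 transpose convolution,
  concatenation with the matching encoder features, then an MDR block
  (whose shortcut provides the residual path). The two decoders are
  parameter-independent; gradients from one head never reach the other's
  decoder, which the test suite asserts.
* **Block dilation default (1, 3).** Only the bottleneck rates are fixed
  by design at (1, 3, 5); inside the blocks, two rates keep the receptive
  field growth while saving one third of the convolution cost. Exact
  channel widths and block counts of the original network are unpublished;
  all counts here are therefore explicit assumptions, and no attempt is
  made to match its parameter count.
* **Normalization variants.** batch / instance / group /
  weight-standardized + group are exposed as a config knob
  (`norm_layer`); batch normalization is the default. Benchmarking the
  variants is out of scope.

## Losses

Per task, the focal Tversky loss over both class channels (ROI and
background): `Σ_c (1 − TI_c)^(1/γ)` with
`TI = (TP+φ)/(TP + α·FN + β·FP + φ)`, α = 0.3, β = 0.7, γ = 1,
φ = 1e−6. Soft probabilities are used during training; α = β = 0.5
recovers `Σ_c (1 − Dice_c)` exactly, which serves as an oracle check.

Multitask combination (default): homoscedastic-uncertainty weighting,
`L_b/σ_b² + log σ_b + L_d/σ_d² + log σ_d`. The uncertainties are
parameterized as s = log σ² (so each task contributes
`exp(−s)·L + s/2`), initialized at s = 0 (σ = 1), and optimized jointly
with the weights — the standard unconstrained, numerically stable form.
Holding the task losses constant, the optimum is σ² = 2L, which the tests
verify by optimizing s alone. The 1/σ² scaling of the logits that appears
in the likelihood derivation is *not* applied at inference; the heads are
plain softmax, and the implemented objective is the final approximated
form above. The per-task log σ term is stored and logged as σ (not s) so
checkpoints are interpretable.

The naive fixed-weight alternative `λ·L_b + (1−λ)·L_d` (λ strictly inside
(0, 1)) and single-task modes (the other decoder absent) support the
ablation studies; a grid utility trains one model per λ under identical
seeds.

## Training

Adam, learning rate 1e−3, batch size 8–10, no augmentation. The loss is
computed over whole batches (pixel sums include the batch axis). Model
selection keeps the epoch with the best validation F-score of the dense
task (the main task), breast in single-breast mode. One master seed
derives the split and shuffling streams; weight initialization is seeded
separately, so training is bit-reproducible on a fixed backend. A
non-finite loss aborts immediately, naming the epoch. The default epoch
budget of the full-scale configuration is 100; the desk-scale recovery
study uses 12 epochs, which its validation curve shows is comfortably past
convergence on phantoms — a runtime choice, not a tuning choice.

The network runs on a small numpy reverse-mode autodiff layer
(`mammodensity.nn`): im2col-based stride-1 dilated convolution (input
gradient computed as correlation with the flipped kernel), exact-scatter
stride-2 transpose convolution, 2×2 max pooling with first-maximum tie
break, and batch/group/instance normalization. Gradients of every operator
are verified against central finite differences in the test suite.

## Preprocessing

Images load as floats scaled by the full range of their stored bit depth
(255 / 65535; DICOM via rescale slope/intercept then the stored bit
depth). Preprocessing follows the segmentation-mask protocol: background
zeroing via the breast mask (idempotent), per-image min–max normalization
(optionally restricted to a region; a constant region yields all zeros
with a warning rather than an error), and bicubic resize to the square
model input. Masks use {0, 255} on disk, {0, 1} in memory (threshold 128
on load), nearest-neighbor resize with center-aligned source sampling, and
stay strictly binary through every operation.

One documented ambiguity: the resize is described both as fixed 256×256
and as aspect-preserving, which conflict for non-square inputs. The
package resizes directly (anisotropically) to the square size and restores
predictions to the native resolution afterwards; no padding is applied.

## Percent density, Otsu baseline, categories

`percent_density` divides raw dense count by raw breast count without
intersecting the masks first — faithful to the defining formula — but
warns and clips to 100 if a predicted dense mask leaks outside the breast,
preserving the [0, 100] invariant. An empty breast mask is an error
(density undefined).

The conventional baseline: zero the background with the breast mask, blur
with an explicit 5×5 Gaussian kernel (σ = 1.1 by the standard
kernel-size rule 0.3·((k−1)/2 − 1) + 0.8), quantize to 8 bits, Otsu
threshold, count pixels above the threshold inside the breast as dense.
The Otsu statistic is computed over breast-interior pixels only: whether
the original protocol included the zeroed background in the histogram is
unstated, and including millions of background zeros would swamp the lower
class; the masked-histogram choice is the defensible one and is tested
against an exhaustive search. The threshold maximizes between-class
variance over the full 256-bin histogram, returning the lowest maximizing
level on ties. A constant breast region yields PD 0 with a warning.

BI-RADS (4th ed.) categories are the four 25-point intervals with
inclusive upper bounds (25.0 → category 1). Reference PD from two readers:
pairs within a ±5 PD-point clinically acceptable difference (CDI) are
averaged; others are retained but flagged and excluded from the reference.

## Agreement statistics

Pearson's r by the product-moment formula with a Fisher-z confidence
interval (SE 1/√(n−3)); the interval method is not prescribed by the
protocol being mirrored, and Fisher z is the standard choice. PD values
are log-transformed before correlation/agreement as log(pd + 0.01) — the
offset (0.01 percentage points, configurable) admits PD = 0, whose
handling is otherwise unspecified. Bland–Altman uses sample (n−1) SDs and
limits at bias ± 1.96 SD; CDI acceptance is always counted on the raw
percentage scale even when the limits are computed on the log scale, and
both are reported.

## Synthetic phantoms

Each phantom is a half-elliptical breast against the left edge (jittered
center and axes), dark background, with dense tissue built by thresholding
a sum of 6 anisotropic Gaussian bumps at the field quantile matching the
target PD — giving irregular, realistic blob borders and a realized PD
within ±2 percentage points of target (re-drawn with more/larger blobs up
to 100 times, then failing loudly). MLO phantoms add a bright triangular
pectoral wedge excluded from the breast mask, reproducing the one
confounder that makes breast-area segmentation genuinely hard. Intensities
(background 0.05, fat 0.35, dense 0.75, pectoral 0.9) are softly blurred
(σ = 1 px) and corrupted with additive Gaussian noise (SD 0.02, clipped to
[0, 1]) *after* the masks are frozen, so ground truth stays exact and the
manifest PD equals mask-counting PD to the last bit.

What the phantoms do **not** emulate: vendor-specific post-processing,
scanner intensity profiles, skin folds, labels/markers, lesions and
calcifications, nipple/abdominal tissue, and the full-resolution texture
spectrum of real fibroglandular tissue. Passing the phantom-recovery tests
therefore demonstrates that the architecture, losses, training loop, and
density derivation are implemented correctly and can recover known ground
truth — not that the model reaches clinical-grade accuracy on real
mammograms, which requires real annotated data.

## Problem sizes

Desk-scale studies are sized for a single CPU: the recovery study uses 250
phantoms (200 train / 50 test) at 64×64 with a width-8, depth-2 model for
12 epochs; the demo pipeline's `tiny` scale uses 36 phantoms and 6 epochs,
`small` 120 and 20. The spatial resolution, widths and epoch counts are
the package's own desk-scale choices; every structural contract
(nesting, determinism, gradient isolation, metric identities) is
scale-independent.

## Known limitations

* The original network's exact widths/block wiring are unpublished;
  parameter counts are not comparable.
* Batch normalization makes eval-time outputs depend on training history
  (running statistics); group/instance normalization avoid this if
  batch-size independence matters.
* The autodiff layer supports exactly the operators the model needs; it is
  not a general framework and runs on CPU only.
* Reader-PD inputs (LIBRA/Quantra-style columns) are consumed as plain CSV
  series; those tools are not re-implemented.
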