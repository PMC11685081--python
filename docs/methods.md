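# Methods

## Problem and model

The package estimates a five-component nutrient label — mass (g), calories
(kcal), fat (g), carbohydrate (g), protein (g) — from a single top-view RGB
photograph of a plated meal. The design separates two concerns:

1. **Where is the food?** A UNet produces a binary food/background mask.
   The encoder applies, per stage, two 3×3 same-padding convolutions with
   ReLU followed by 2×2 max pooling, doubling the channel count each stage;
   a bottleneck block doubles channels once more; the decoder mirrors the
   encoder, upsampling with kernel-2 stride-2 transposed convolutions and
   concatenating the same-resolution encoder feature map (skip connection)
   before each pair of convolutions. A 1×1 convolution maps to a single
   food-vs-background logit per pixel. Input sides must be divisible by
   2^n_stages so pooling is exact.
2. **How much of what is on it?** Pixels outside the (predicted or
   ground-truth) mask are zeroed and the masked image goes to a regression
   network: a convolutional backbone, one Squeeze-and-Excitation block on
   the backbone's final feature map, global average pooling, and three
   fully connected layers emitting the five values. The SE block computes
   channel descriptors by global average pooling (squeeze), passes them
   through a bottleneck of two bias-free linear layers with ReLU then
   sigmoid (excitation, reduction ratio r), and multiplies each channel by
   its weight (recalibration). Masking first means background clutter
   cannot contribute features; the 2×2 ablation grid (original vs segmented
   input × SE on/off) quantifies exactly that.

### Loss and metrics

Training the regressor minimizes the sum-normalized multi-task loss
`L = Σ_m l_m` with `l_m = Σ|ŷ−y| / Σy` per nutrient. Normalizing by the sum
of true values makes each subtask scale-free; mass and calories, an order
of magnitude larger than the macros, then cannot drown out the fat/carb/
protein gradients. During training the sums run over each mini-batch; at
evaluation they run over the whole test set. `l_m` is algebraically
identical to PMAE/100 on the same data (the two 1/N factors cancel), a
property the test suite asserts to machine precision. If a batch's true
values for some nutrient sum to zero, the loss for that subtask falls back
to Σ|ŷ| (with a warning) so training stays finite; with the default
generator this cannot occur for mass or calories and is vanishingly rare
for the macros.

Segmentation is scored by Dice, Jaccard, precision and recall from pixel
confusion counts with food as the positive class. When a denominator is
zero: both masks empty scores 1.0, otherwise 0.0 with a warning. Regression
is scored by per-nutrient PMAE/MAE/MSE/RMSE/R² and the unweighted mean of
the five PMAEs; R² is NaN (with a warning) when the truths have zero
variance. After every regression epoch the model is evaluated on the test
set and the snapshot with the lowest mean PMAE is reported (ties go to the
earliest epoch).

## Synthetic scene generator

The generator emulates the statistics of real annotated top-view dish
photographs rather than their appearance:

- a light elliptical plate (radius 30–40% of each image side) on a darker
  textured background;
- 1–4 ingredient blobs inside the plate — random star-convex polygons with
  harmonic boundary perturbations — each drawn from a fixed 12-entry
  palette of distinct colors with per-pixel Gaussian texture jitter;
- a food area fraction targeted uniformly in 5–30% of the frame (the range
  that dominates real dishes), with resampling when a draw lands outside
  half-to-1.2× the target band;
- 0–3 (configurable) food-colored distractor blobs strictly off the plate,
  never part of the ground-truth mask — these make the benefit of
  segmentation-first training measurable;
- labels computed exactly from provenance: each palette entry carries a
  density vector (mass g/pixel, kcal/g, and fat/carb/protein g per g), so
  mass = Σ areaₖ·mppₖ and the rest follow linearly. The densities are
  loosely modeled on everyday foods and deliberately reproduce the
  magnitude asymmetry (mass, calories ≫ macros) that motivates the
  normalized loss;
- optional multiplicative Gaussian label noise with configurable
  coefficient of variation, truncated at zero; the default is noiseless so
  labels are exact functions of pixel areas.

What this does **not** emulate: photographic texture and lighting,
occlusion and stacking of foods, depth cues, ingredient shapes beyond
star-convex blobs, or label error from real weighing and database lookup.
Passing the synthetic experiments therefore demonstrates that the
architecture, loss, masking and evaluation machinery are correct and that
the pipeline learns the area-to-nutrient mapping it is designed for — not
that the absolute accuracies transfer to real photographs.

## Numerical engine

The networks run on a small reverse-mode autodiff engine over NumPy float32
arrays (`nutriseg.nn`): broadcasting arithmetic, matmul, im2col-based 2-D
convolution, non-overlapping kernel-2 stride-2 transposed convolution, 2×2
max pooling, channel concatenation, ReLU/sigmoid, reductions, and a
numerically stable binary-cross-entropy-on-logits. Gradients are checked
against central finite differences in the test suite (with fixed random
linear projections of structural-op outputs, for which central differences
are exact up to rounding). Weights use He initialization from an explicit
seeded generator; optimization is Adam (β₁=0.9, β₂=0.999, ε=1e-8) with the
learning rate decayed by 0.99 per epoch. Single-threaded NumPy/BLAS makes
runs bitwise reproducible from one seed on a given platform; across BLAS
implementations the usual floating-point caveats apply.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| split fraction / multiple | 0.8, multiples of 8 | train size = nearest multiple of 8 to 0.8·N, ties to the larger train set; e.g. 3,224 ids split 2,576/648 |
| run seed | 42 | single seed from which every random process derives |
| batch size | 8 | shared by both training loops |
| segmentation epochs / lr | 50, 1e-3 | full-scale convention; desk-scale recipes use 10–14 epochs at 2e-3 |
| regression epochs / lr | 300, 1e-4 | full-scale convention; desk-scale recipes use 15–40 epochs at 1e-3 |
| lr decay | 0.99 per epoch | exponential schedule, lr_e = lr₀·0.99^e |
| UNet stages / base channels | 4 / 64 | full-scale; tests and recipes use 2 / 8, which suffices at 64×64 |
| SE reduction r | 16 (4 for the small backbones) | bottleneck C/r rounded up when it does not divide |
| FC head widths | C→512→128→5 | one shared head for all five outputs |
| augmentation | horizontal flip p=0.5, optional random crop | training only; evaluation uses the native image (or center crop) |
| mask threshold | 0.5 on the sigmoid | standard binarization of the food probability |

## Study sizes for desk-scale runs

The recipes in `nutriseg.experiments` use 64×64 scenes, a 2-stage base-8
UNet and the 3-stage "small" CNN backbone so each completes in minutes on
one CPU core: segmentation recovery trains on 300 scenes for 14 epochs
(held-out Dice typically 0.94–0.95); nutrient recovery trains on 400 of
500 dishes for 40 epochs (held-out mean PMAE typically 12–16%, against a
<0.1% linear-readout floor computed by least squares from per-ingredient
color areas); the ablation trains 200-dish runs for 15 epochs per cell over
three seeds and compares medians. These sizes are the package's choices for
quick, repeatable experiments; the full-scale conventions in the table
above remain the defaults of the config objects.

## Design choices where the design was open

- **Segmentation loss**: pixelwise binary cross-entropy on logits — the
  natural choice for a single-foreground problem; Dice-style losses were
  not needed at the area fractions the generator produces.
- **Upsampling**: transposed convolution (kernel 2, stride 2). Because
  stride equals kernel size the output blocks do not overlap, which avoids
  checkerboard artifacts and has an exact, cheap backward pass.
- **One shared FC head** emitting all five outputs rather than five
  per-nutrient towers; the shared trunk plus the normalized loss already
  balances the subtasks.
- **SE placement**: once, on the backbone's final feature map.
- **Outputs**: unconstrained during training, clamped at zero for
  reporting, since labels are non-negative.
- **Input mode default**: the regressor trains on UNet-predicted masks
  (`segmented-predicted`), with `segmented-gt` and `original` available;
  the ablation recipe uses ground-truth masks to isolate the masking
  effect from segmenter quality.
- **Metadata dialect**: plain CSV `id, calories, mass, fat, carb, protein`
  with an optional header auto-detected by a non-numeric second field;
  masks persist as single-channel 0/255 PNGs, gray values thresholded at
  128 with a warning.
- **"mass" vs "weight"**: the two names denote the same quantity; the
  package exposes `mass` everywhere.

## Known limitations

- The synthetic domain is far easier than real photographs: colors identify
  ingredients almost uniquely, so desk-scale accuracies overstate what the
  same architecture achieves on real data.
- The NumPy engine is single-threaded and CPU-bound; full-scale settings
  (4-stage base-64 UNet, 300 epochs) are impractical on it and are provided
  as configuration conventions, not as runnable defaults.
- Nutrient labels are linear in pixel areas by construction; real dishes
  have depth, density variation and occlusion the generator does not model,
  so mass prediction in particular is optimistic.
- The empty-mask and zero-denominator conventions (score 1.0 when both
  masks are empty; subtask loss Σ|ŷ| when truths sum to zero) are package
  conventions chosen to keep metrics total and training finite.
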