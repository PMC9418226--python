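# Methods

## Problem setting

Atrophic macular disease — geographic atrophy (GA) in age-related
macular degeneration (AMD) and the atrophy of Stargardt disease — shows
on fundus autofluorescence (FAF) imaging as hypo-fluorescent regions
where the retinal pigment epithelium and its lipofuscin fluorophores
have been lost.  The package addresses two supervised tasks on 2-D
grayscale FAF-like images: (1) baseline lesion segmentation against
expert-style binary masks, and (2) 12-month progression prediction, in
which the baseline image is trained against the follow-up lesion mask
after that mask has been rigidly registered into the baseline frame.

## Segmentation networks

Both networks are U-shaped fully convolutional nets: `depth` levels of
(two 3×3 convolutions + ReLU, then 2×2 max pooling), a two-convolution
bottleneck, and a symmetric decoder that 2× nearest-neighbour-upsamples
the coarser features, convolves them to the level's width, concatenates
the same-resolution encoder features through a skip connection, and
applies two more 3×3 conv + ReLU layers.  A 1×1 convolution with a
logistic activation produces the one-channel soft-label probability
map.  Channel widths double per level from `base_filters`.

The *attended* variant inserts a trainable attention gate into every
skip connection.  With skip features `x` (F_l channels) and gating
signal `s` (F_s channels; the decoder's coarser features after
upsampling and the up-convolution, so `s` is spatially aligned with
`x`), the gate computes per pixel

    a     = psi . relu(W_x' x + W_s' s + b_g) + b_psi
    alpha = 1 / (1 + exp(-a / T))
    gated = alpha * x

with `W_x ∈ R^{F_l×F_int}`, `W_s ∈ R^{F_s×F_int}`, `psi ∈ R^{F_int}`,
biases `b_g ∈ R^{F_int}`, `b_psi ∈ R`.  `alpha` is a single channel per
pixel, broadcast across the channels of `x` (psi maps to a scalar), and
`F_int = max(1, floor(F_l · f_int_ratio))` with `f_int_ratio = 0.5` by
default.  The bounded logistic is used for σ₂ — the form consistent
with alpha being a probability in [0, 1] — and every architecture
descriptor JSON records this choice explicitly.  `T` is the soft-label
temperature: `T → ∞` drives every coefficient to 0.5 (softest labels),
small `T` sharpens them; the default `T = 1` is used everywhere unless
configured otherwise.  With `alpha ≡ 1` the attended network reduces
exactly to the plain one, which pins down the topology.

### Training

Pixelwise binary cross-entropy on the soft output is the default loss
(a soft-Dice loss is available via `loss="dice"`); Adam with learning
rate 1e-3, batch size 4, 30 epochs, and fixed-seed He-uniform
(fan-in) weight initialization.  Gate biases start at zero, so every
coefficient begins at alpha = 0.5 and training moves it in either
direction.  An "open-gate" variant (b_psi biased positive so alpha
starts near 1, the identity-start idiom of forget-gate biases) was
evaluated and rejected: it neither changed the attended-vs-plain
comparison at desk scale nor preserved the foreground-focused
orientation of the trained attention maps.  Early stopping (patience 10 on
validation loss) is active only when a validation set is supplied, and
the best-validation checkpoint is restored.  All of these are recorded
in the estimator's parameters and the experiment manifest; none are
claimed to be the original study's values, which were not published.
The implementation is plain numpy: convolutions as im2col + float32
GEMM with reusable scratch buffers, explicit backward passes for every
operation (each was verified against central-difference gradients), and
max-pool argmax "switches" recorded on every forward pass.

## Synthetic scenes

Each scene is a deterministic function of its seed and emulates exactly
the image features the pipeline depends on: a smooth bright background
(~0.62 with low-frequency illumination variation), a recursive
branching vessel tree rendered dark (its branch points are the
registration landmarks), one or several irregular hypo-fluorescent foci
(intensity `hypo_level` × background, default 0.35; boundary roughened
by stochastic accretion; edges optionally Gaussian-blurred for the
poorly demarcated Stargardt-like phenotype), a dark optic-nerve-head
disc near the image edge as a false-positive hazard, scattered shallow
hypo-fluorescent distractor spots that are *not* part of the lesion
label (6 by default, at 0.72× background — emulating the scattered
autofluorescence reductions of incomplete RPE loss seen around and away
from frank atrophy; they give the models a genuine false-positive
hazard to suppress), additive Gaussian speckle noise (σ = 0.02), and an
optional black border at the image bottom.  Defaults model the
multi-focal case (3 foci, radii 5.5–11% of the canvas).

The Month-12 mask grows the baseline mask by stochastic boundary
accretion — random boundary pixels, weighted by their number of lesion
neighbours, are added until the area reaches
`round(area · (1 + growth_fraction))` — so growth is monotone
(never shrinking), spatially irregular, and hits its target area
exactly.  `growth_fraction` defaults to 0.3 over one interval; the
literature does not quantify typical 12-month growth, so this is a
free, documented parameter rather than a reproduced value.  The
follow-up acquisition is simulated by warping the follow-up image and
mask with a known random rigid transform (|θ| ≤ 6°, |t| scaled to the
canvas) plus fresh noise, and the transform is stored as ground truth.

What the generator does **not** emulate: photorealistic FAF texture,
hyper-fluorescent rims, media opacity, device vignetting, non-rigid eye
motion, or disease biophysics.  Tests passing on these scenes therefore
demonstrate the correctness and internal consistency of the pipeline —
not clinical-grade performance on real FAF data.

## Preprocessing

The bottom black border is the maximal run of terminal rows with mean
intensity ≤ 0.02 (rows containing bright pixels terminate the run); it
is cropped from the image and the label *before* resizing, and both are
then resized to a constant square size (bilinear for images,
nearest-neighbour for masks, which stay strictly {0, 1}).  Intensities
are linearly rescaled to [0, 1] by bit depth on read; this rescale is a
package choice, exposed as a flag.

## Longitudinal registration

Landmarks are junctions of the skeletonized vessel map: Sato ridge
enhancement of dark tubular structures (σ = 1–3 px) → Otsu threshold →
removal of small components → skeletonization → skeleton pixels with
≥ 3 skeleton neighbours, merged per connected junction cluster
(3 neighbours → bifurcation, ≥ 4 → crossover).  Correspondence and
outlier rejection are solved jointly by RANSAC over distance-compatible
landmark pairs (200 iterations, fixed seed, inlier radius 5 px,
baselines < 15 px skipped, candidate rotations limited to ±20°),
followed by a mutual-nearest-neighbour re-match and a closed-form 2-D
orthogonal Procrustes fit constrained to det = +1 (no reflection, no
scale).  Because junction centroids localize only to about a pixel, a
final refinement maximizes the normalized cross-correlation of the two
Sato ridge maps over (θ, t_row, t_col) with Powell's method, reaching
sub-0.2° / sub-0.5-px accuracy on the synthetic scenes.  Coordinates
are 0-based (row, col) at pixel centres; rotations are about the
geometric image centre, and transforms serialize to JSON with exactly
those conventions.  Masks are warped with nearest-neighbour
resampling, zero-filled outside the canvas.

A coincident (or symmetric) landmark configuration leaves the
rotation genuinely ambiguous and raises an error; with the det = +1
constraint, merely collinear but distinct points remain well-posed and
are accepted.

## Cross-validation protocol

A validation set of fixed size is chosen once (whole subjects whose
sample counts sum exactly to the requested size) and kept identical
across folds.  The remaining subjects are dealt largest-first to the
fold with the most remaining capacity, producing pairwise-disjoint
rotating test sets balanced to within one sample whose union covers all
non-validation samples; everything else trains.  Both eyes of one
subject are never split across train and test, and validation subjects
appear in no train or test set (the stricter reading of the grouping
rule).  With 90 single-eye subjects / 8 folds / 10 validation samples
this yields 70 train, 10 validation, 10 test per fold; with 206 samples
from 127 subjects / 22 validation it yields 161/22/23.

## Evaluation and statistics

From pixel confusion counts: accuracy = (TP+TN)/total, sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP), Dice = 2TP/(2TP+FP+FN), IoU =
TP/(TP+FP+FN); the identity Dice = 2·IoU/(1+IoU) is test-pinned.
Undefined ratios are flagged, never silently zeroed; when reference and
prediction are both empty, Dice, IoU and sensitivity are reported as 1
(a correct prediction of a lesion-free image is not penalized) and
flagged.  Per-image metrics are averaged across images within folds and
then across folds by default (configurable, since the aggregation order
is an open choice).  Model comparisons use the percent difference
(m₂ − m₁)/m₁ on unrounded aggregated means, the two-sided Mann–Whitney
U test (exact when the pooled sample has ≤ 16 observations and no
ties, otherwise the normal approximation with tie and continuity
corrections; the method used is recorded), and 95% confidence
half-widths 1.959964 · sd/√n with the normal quantile (the spreadsheet
convention; a Student-t variant is available behind a flag).

## Feature visualization

*Attention heatmaps* are a gated level's raw alpha map bilinearly
upsampled to input resolution; the raw values are preserved alongside a
monotone min–max display rescale, and quantitative tests consume only
the raw map.  *Deconvnet reconstructions* (plain model only) run the
encoder blocks in reverse from a chosen level: ReLU, transposed
convolutions sharing the forward kernels (flipped — no reconstruction
weights are trained), and switch-unpooling that places each retained
maximum back at its recorded argmax location and zeroes the rest.
Channels are collapsed by the sum of absolute values for display.

## Problem sizes used by the test and acceptance runs

Desk-scale training uses 64 multi-focal 128×128 scenes in the
Stargardt-like hard configuration (4 foci, edge blur σ = 3 px,
lesion intensity 0.55× background, default distractors and ONH),
depth-3 / base-8 models, 30 epochs, with 5 held-out scenes; the
acceptance test suite trains both variants with three seeds and
compares median held-out Dice, and the acceptance script trains one
seed per variant.  On the easy well-demarcated default scenes both
variants saturate near Dice 0.96 and the comparison is uninformative;
the hard configuration is the regime the attention mechanism exists
for.
Registration recovery uses 192×192 scenes with |θ| ≤ 10°, |t| ≤ 20 px
(100 scenes in the test suite, 40 in the script).  These sizes are the
package's own desk-scale choices; full-scale 768×768 configurations are
expressible through the same interfaces.

## Known limitations

* Performance figures on synthetic scenes say nothing quantitative
  about clinical FAF data; the published clinical metric values are not
  reproducible without the private datasets.
* At desk scale the attended-vs-plain comparison is a statistical tie:
  both variants reach the fixture's performance ceiling (median
  held-out Dice ≈ 0.94, gap within per-seed spread), because the
  residual error there is boundary ambiguity from the blurred lesion
  edges, which skip-connection gating does not address.  The clinical
  advantage reported for attention gating operates on failure modes
  (gross under-/over-segmentation) that the small synthetic task does
  not reliably elicit.
* The numpy implementation is CPU-bound; large-scale training (768 px,
  many epochs) is possible but slow.
* Registration assumes a rigid motion model and a visible vessel tree;
  images without detectable vessels yield an empty landmark set and a
  warning rather than a transform.
* The attention-localization property (alpha concentrating on lesions)
  is a statistical tendency of trained models, not a guarantee per
  image.  It emerges at the deepest gated level (the default
  visualization level); at the finer levels the trained coefficients
  often adopt the mirror orientation, suppressing lesion-interior
  high-resolution detail instead of background — an equally valid
  optimum of the training objective, since the decoder can compensate
  for either sign.
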