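# fafseg

Attention-gated segmentation and 12-month progression prediction of
atrophic retinal lesions on fundus-autofluorescence (FAF)-like images.

Geographic atrophy (GA) in age-related macular degeneration and the
atrophic lesions of Stargardt disease appear on FAF imaging as
hypo-fluorescent regions caused by the loss of the retinal pigment
epithelium.  Quantifying these lesions — and anticipating where they
will grow — matters for clinical research, but manual delineation is
slow and clinical FAF datasets are rarely shareable.  `fafseg` provides
the full analysis pipeline for this problem, exercised end-to-end on a
bundled synthetic FAF scene generator so that every stage is testable
without patient data.

## The model

The core is a U-shaped fully convolutional network — a contracting
encoder (two 3×3 conv + ReLU per level, 2×2 max pooling), a symmetric
expanding decoder, and skip connections — with a **trainable attention
gate** on every skip connection.  For skip features
*x*ᵢˡ ∈ ℝ^{F_l} and a gating signal *s*ᵢˡ ∈ ℝ^{F_s}
(the upsampled coarser decoder features), the gate computes per pixel *i*

    aᵢˡ = ψᵀ σ₁(W_xᵀ xᵢˡ + W_sᵀ sᵢˡ + b_g) + b_ψ        (σ₁ = ReLU)
    αᵢˡ = σ₂(aᵢˡ) = 1 / (1 + exp(−aᵢˡ / T))
    gatedᵢˡ = αᵢˡ · xᵢˡ

so background activations are suppressed before they reach the decoder,
and the gradients flowing back through the skip are down-weighted in
irrelevant regions.  `T` is a soft-label temperature (default 1; larger
values soften α toward 0.5).  The final 1×1 convolution with a logistic
activation yields a soft-label probability map; thresholding at 0.5
gives the binary lesion mask.  The plain U-Net is the identical
topology without gates, and with every α forced to 1 the two networks
are numerically identical — a property the test suite checks.

The network, its backward pass and Adam are implemented directly on
numpy (float32, im2col + GEMM convolutions), so the package has no
deep-learning-framework dependency and runs on any CPU.

Around the model the package provides:

* **`fafseg.synthetic`** — scenes with dark branching vessel trees,
  single- or multi-focal hypo-fluorescent lesions, an optic-nerve-head
  confounder, scattered unlabeled hypo-fluorescent distractor spots,
  speckle noise, black bottom borders, monotone 12-month lesion growth
  and a known rigid acquisition shift.
* **`fafseg.preprocessing`** — black-border removal and resizing to a
  constant square size (crop before resize; nearest-neighbour for masks).
* **`fafseg.registration`** — rigid alignment of follow-up images to
  baseline from vessel-junction landmarks (skeleton bifurcations and
  crossovers), with RANSAC correspondence and dense ridge-map
  refinement; the transform is then applied to the follow-up label.
* **`fafseg.crossval`** — grouped rotating 8-fold cross-validation with
  a fixed validation set; both eyes of a patient always stay on the
  same side of a split.
* **`fafseg.metrics`** — accuracy, sensitivity, specificity, Dice, IoU;
  percent differences, Mann–Whitney tests and normal-quantile 95% CIs.
* **`fafseg.visualization`** — attention-coefficient heatmaps and
  deconvnet reconstructions (switch unpooling + transposed shared
  kernels).

## A worked example

```python
import numpy as np
from fafseg import AttentionUNetSegmenter, LesionSpec, SceneSpec, generate_dataset

spec = SceneSpec(canvas_size=(64, 64),
                 lesion=LesionSpec(n_foci=2, focus_radii=[11.0, 9.0]))
scenes = generate_dataset(16, spec, seed=7)
X = np.stack([s.image_t0 for s in scenes[:12]])
y = np.stack([s.mask_t0 for s in scenes[:12]])
X_test = np.stack([s.image_t0 for s in scenes[12:]])
y_test = np.stack([s.mask_t0 for s in scenes[12:]])

model = AttentionUNetSegmenter(depth=2, base_filters=8, epochs=25, random_state=0)
model.fit(X, y)
print(f"held-out mean Dice: {model.score(X_test, y_test):.3f}")
print(f"final training loss: {model.history_['train_loss'].iloc[-1]:.4f}")
```

prints

```
held-out mean Dice: 0.878
final training loss: 0.1344
```

i.e. after 25 epochs on twelve 64-pixel scenes the attended model
recovers ~88% of the lesion area (by Dice overlap) on four unseen
scenes.  For progression prediction, pass the registered Month-12 masks
as `y`; `fafseg.crossval.train_fold(..., target_label="t12_registered")`
and the `fafseg run` CLI wire the full protocol (simulate → preprocess →
register → folds → train → evaluate → visualize) together.

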