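# mpdc — multi-perspective dynamic consistency segmentation

Semi-supervised semantic segmentation of 2-D medical image slices
(cardiac MRI, prostate MRI, colonoscopy polyps and similar) for settings
where only a small fraction of scans carries pixel-level annotation.
The package is aimed at researchers who want a fully tested, CPU-friendly
reference implementation of multi-perspective consistency training that
can be exercised end to end on built-in synthetic data — no downloads,
no GPU — and applied to real slice datasets through the standard
PNG/NIfTI/HDF5 readers.

## The method

Three encoder–decoder branches look at every image from different
perspectives:

* **positive** branch: a U-Net (bilinear up-sampling) trained to predict
  the target regions, `P_pos = softmax(O_pos)`;
* **reverse** branch: an independent U-Net (transposed-convolution
  up-sampling) whose raw scores are negated before softmax,
  `P_rev = softmax(−O_rev)`, so it learns background-region features
  while being supervised against the *unmodified* ground truth;
* **fusion** branch: a decoder fed by the Perspective Fusion Module,
  `f_fus = f_pos − softmax(−f_pos) ⊙ softmax(f_rev)`, which damps
  channel responses the two perspectives agree on and amplifies the
  disputed (boundary) ones.

Each branch pays a soft Dice loss on the labeled half of the batch.  On
the unlabeled half, a dynamic threshold

```
γ_0 = 1/C,   γ_i = min(γ_i^pos, γ_i^rev),
γ_i^b = (1 − λ) γ_{i−1}^b + λ · mean_batch(mean_pixels(max_class P_b)),   λ = i / i_max
```

splits pixels into a *consistent* part (both branches' max confidence
strictly above γ) and an *inconsistent* part.  Consistent pixels get
pairwise cross-pseudo supervision — two cross-entropy terms below a mean
confidence of 0.95, all six pairwise terms above it.  Inconsistent
pixels get a direction-consistency loss that pulls each branch's
low-confidence predictions toward the other branch's stop-gradient
high-confidence predictions.  A feature-consistency term ties
channel-compressed (`mean_c |f|²`) encoder and decoder feature maps per
level.  The total objective is the unweighted sum of all six components.

Evaluation follows the field's four-metric protocol: Dice and Jaccard
(percent) for region overlap, 95th-percentile Hausdorff distance and
average surface distance (voxels) for boundary quality, computed per
class on re-stacked scan volumes.

The network and losses run on a compact reverse-mode automatic
differentiation engine over numpy (`mpdc.autodiff`) whose every operator
is gradient-checked against finite differences in the test suite.

## Worked example

`examples/04_semi_supervised_training.py` trains the full pipeline and a
supervised-only baseline (identical labeled data, batches and budget) on
the built-in synthetic dataset — 12 scans of 4 low-contrast 32×32
slices, 10% of training scans labeled — and prints:

```
dataset: 4 labeled / 24 unlabeled training slices, 8 val, 12 test
supervised-only test Dice: 93.20%
full MPDC test Dice:       93.71%  (gain +0.51 points from unlabeled data)
final dynamic threshold 0.988; 91% of pixels consistent at the end (the consistent fraction grows as the branches converge)
```

The gain is the point of the method: the consistency machinery extracts
signal from the 24 unlabeled slices the baseline ignores.  The threshold
trajectory (0.5 → ~0.99) shows the confidence bar rising as the branches
converge; the growing consistent fraction is the curriculum effect of
dynamic thresholding.  The other examples each exercise one capability:
data generation, the forward pass and decoupling, the individual loss
components, and the evaluation metrics.

A thin CLI wraps the same library calls:

```bash
mpdc synth --spec spec.yaml --out data/
mpdc train --config cfg.yaml --data data/ --out run/
mpdc eval  --ckpt run/last.npz --config cfg.yaml --data data/ --split test
mpdc ablate --axis threshold --config cfg.yaml --data data/ --out abl/
```

## Layout

* `src/mpdc/` — library: `autodiff`, `network`, `decoupling`, `losses`,
  `trainer`, `metrics`, `data`, `synthetic`, `experiments`, `cli`.
* `examples/` — one narrative script per capability.
* `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and known limitations.
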