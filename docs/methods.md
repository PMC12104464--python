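# Methods

## Model

Two independent U-Net encoders (positive and reverse perspective) and
three decoders share no parameters unless the shared-encoder ablation is
switched on.  Every level is a pair of 3×3 conv → batch-norm → ReLU
blocks; channel width doubles per level from `base_width`.  The positive
decoder up-samples by bilinear interpolation followed by a 1×1
channel-reducing convolution (keeping parameter counts comparable to the
transposed-convolution decoders); the reverse and fusion decoders use
2×2/stride-2 transposed convolutions.  Weights are Kaiming-normal with a
seeded generator, so a seed fully determines the initial state.

The reverse branch's confidence map is the softmax of its *negated*
scores; its supervised Dice loss is computed against the unmodified
ground truth (prediction-map inversion).  The ground-truth-inversion
variant — flip the one-hot truth and score `softmax(O_rev)` against it —
is retained as an ablation arm.

**Where fusion applies.** The fusion decoder needs skip inputs, so the
Perspective Fusion Module is applied independently at every encoder
level (bottleneck and each skip) and the fusion decoder consumes the
fused pyramid.  This is the main interpretive choice in the
architecture; a `fuse_levels: bottleneck_only` switch feeds unfused
skips instead.  The softmax inside the fusion operator runs over the
channel axis — the only axis with class-like semantics — per pixel.
Gradient bookkeeping follows from the wiring: the positive supervised
loss reaches only the positive encoder/decoder, the reverse one only the
reverse pair, and the fusion loss reaches the fusion decoder plus both
encoders.  The test suite asserts these reachability sets.

## Dynamic decoupling

The threshold statistic per branch is the per-pixel max-class
confidence, averaged over pixels, then over batch items.  (Taking a max
over pixels instead would saturate to ~1 immediately and make the
threshold useless; mean-of-max is the established dynamic-threshold
statistic.)  The EMA weight is λ = i/i_max, so early updates barely move
the threshold and the final update replaces it outright.  Comparisons
with γ are strict; pixels tied exactly at γ fall to the inconsistent
part, and inconsistent pixels where the two branches' max confidences
tie exactly belong to neither high-confidence mask (no defined pull
direction).  The threshold is updated from the unlabeled half of the
batch only — the decoupling machinery targets unlabeled consistency —
and is checkpointed so training resumes bit-identically.  A fixed
threshold (0.25/0.5/0.9) can replace the EMA for the ablation.

## Losses and their conventions

* Soft Dice with ε = 1e-5 in numerator and denominator, averaged over
  classes and labeled items.
* Direction consistency: mean squared difference over the pixels of each
  high-confidence mask and all classes; the high-confidence operand is
  detached (stop-gradient), which the tests verify via autodiff.
* Cross-pseudo supervision: cross-entropy of scores (after softmax)
  against the comparator branch's argmax pseudo-labels, averaged over
  contributing pixels (not the grid) so masked losses are
  scale-comparable across batches.  The 0.95 gate compares the batch
  mean of the two branches' averaged per-pixel max confidence.  In the
  low-confidence arm, each CE term is restricted to consistent pixels
  where the comparator branch is strictly more confident than the
  supervised one — the comparator's reliable region.
* Feature consistency: channel compression is `mean_c |f|^p` with p = 2;
  each level's squared difference is averaged over pixels (a strict-sum
  mode is selectable) to decouple the magnitude from resolution, and the
  positive and reverse branches' losses are added.  Encoder level m is
  paired with the decoder output at the same resolution; the bottleneck
  has no decoder counterpart and is excluded.
* The total is the unweighted sum of all six components; a weight block
  exists for experiments but defaults to (1, 1, 1, 1).

## Training

SGD with lr 0.01, momentum 0.9, weight decay 5e-4 — constant lr by
default, with an optional poly-decay schedule switched off.  Batches put
labeled items first (loss masking is positional); both pools are
sampled cyclically with a reshuffle per epoch.  Augmentation is
horizontal/vertical flips (p = 0.5 each) and rotations by random
multiples of 90°, identical for image and label; the 90° restriction
avoids interpolation artifacts in label maps.  Validation (Dice of the
positive head, the default inference head since the choice of final head
is otherwise open) runs every `val_interval` iterations and selects the
best checkpoint; one optimizer covers all five parameter sets.  A single
seed drives weight init, sampling and augmentation, making two runs with
the same configuration bit-identical — the determinism contract the
tests enforce for 100 steps and across a checkpoint save/load.

## Synthetic data

The generator emulates the low-contrast, blurred-boundary regime the
fusion branch targets: per slice, each non-background class is a union
of 1–3 random ellipses; intensities are class plateaus separated by a
configurable contrast gap, Gaussian-blurred at the boundary and
corrupted with additive noise; labels stay exact.  Foreground fraction
is kept inside [0.02, 0.5] so Dice stays informative, and increasing the
boundary blur provably (and, in the tests, monotonically) degrades a
naive Otsu-threshold oracle — the difficulty knob.  The generator's
default is 20 scans × 10 slices at 64×64 with two classes.  What it does
*not* model: anatomical shape priors, scanner intensity distributions,
inter-slice correlation beyond sharing a generator stream, multi-organ
context.  Passing tests on this data therefore demonstrate the training
machinery works and the consistency signal is exploitable — not clinical
performance.

## Desk-scale study conditions

The stochastic comparisons (tests and `scripts/acceptance.py`) run on a
reduced instance chosen to keep a full four-arm, three-seed study within
minutes on one CPU core: 12 scans × 4 slices at 32×32, 10% of training
scans labeled (one scan), a depth-3/width-8 network, 300 iterations of
batch 8 with 4 labeled — the labeled:unlabeled ratio of the reference
schedule at 1/25 of its iteration count.  Comparisons ask for
qualitative directions by majority over three seeds (semi-supervised
gain over supervised-only; dynamic threshold ≥ fixed 0.5; three branches
≥ two), not for margins.

## Known limitations

* At this scale, consistency training occasionally collapses on an
  unlucky seed: with a single labeled scan the branches can agree
  confidently on a degenerate all-foreground labelling that the four
  labeled slices cannot pull back, and every consistency arm inherits
  it.  This is the classic confirmation-bias failure mode of
  pseudo-label methods; the majority-over-seeds acceptance design treats
  it as the expected tail, and the 50k-iteration reference schedule
  (λ ramping 100× slower) makes it far less likely at full scale.
* Margins between arms at desk scale are fractions of a Dice point;
  only their direction is meaningful.
* The implementation is 2-D only and single-channel by default (RGB
  inputs are collapsed to luminance unless configured otherwise); no
  DICOM ingestion; no cross-scanner intensity harmonisation.
* The 95HD convention (95th percentile of pooled directed boundary
  distances) is one of several in the literature; values are comparable
  within this package, not necessarily across papers.  Empty
  prediction/truth cases score the volume diagonal and are counted in
  the report rather than silently dropped.
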