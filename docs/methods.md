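# Methods

This note records the models and procedures `spermfusion` implements, the
defaults it ships with and why, what the synthetic generators do and do not
emulate, and the numerical conventions that make runs reproducible.

## Problem setting

The target task is fine-grained classification of single-cell sperm
morphology images into 18 classes (normal morphology plus head, neck and
tail abnormalities) under severe class imbalance: in the reference
distribution the largest class (AmorphHead) holds 3,572 of ~18.5k samples
(~19.4%) and the smallest (LongTail) 42 (~0.2%). Rather than training CNNs
end to end, the pipeline treats CNN backbones as frozen embedding extractors
and concentrates modelling effort on how to *combine* embeddings (feature
fusion) and classifier outputs (decision fusion).

A note on the reference class table: the printed per-class counts sum to
18,446 while the stated collection size is 18,456, and a few printed
percentage cells are inconsistent with both totals (e.g. CurlyTail 7.76% vs
a recomputed 7.82%). The `ClassTable` fixture therefore stores the counts
verbatim and recomputes shares (round-half-up, two decimals) against a
configurable denominator, defaulting to the stated 18,456. The package does
not attempt to reconcile the discrepancy; tests assert only rows whose
printed value recomputes exactly.

## Pipeline stages

### Feature extraction

A backbone maps an image stack to `(penultimate features, logits)`. The
penultimate (second-to-last fully connected) layer's activations are the
embedding; the contract requires that applying the backbone's own
classification head to the returned features reproduces the returned logits
(checked to 1e-5). EfficientNetV2-S/M/L adapters (1280-dim penultimate
layer) are optional torch-based plugins; the reference backbone `TinyCnn`
(2 conv blocks, average pooling, a fully connected penultimate layer of
configurable width, fixed He-scaled seeded weights) exercises the same
contract on the CPU. Adapters resize inputs to their expected side.

### Dense reduction (1280 → 128, ReLU)

The reduction layer `z = max(0, W x + b)` is trained post hoc on frozen
features — the alternative (joint training with the backbone) would couple
the stages and require GPU training, so the layer gets its supervision from
a temporary linear softmax head optimized by cross-entropy and discarded
afterwards. Defaults: batch 64, ≤200 epochs, Adam at 1e-3, early stopping on
a 10% validation split with patience 10, Glorot-uniform init, all seeded.
The rectifier is applied identically at training and inference.

### Feature-level fusion

Concatenation along the feature axis, no rescaling (standardization is a
classifier-side responsibility, applied inside each `fit_*` on training rows
only). Part order is fixed (S, M, L) for reproducibility; bookkeeping
records each part's contiguous column block so fusion is losslessly
invertible. The canonical grid is the three pairwise combinations plus the
triple.

### Classifiers

All three emit per-class probability rows aligned on an identical,
alphabetically sorted class order — the prerequisite for soft voting.

* **SVM (one-vs-rest, RBF).** Standardize; select (γ, C) by mean inner-CV
  accuracy over a grid (defaults γ ∈ {scale, 1e-3, 1e-2, 1e-1} ×
  C ∈ {0.1, 1, 10, 100}, 3 inner folds; "scale" = 1/(d·var)); ties prefer
  smaller C then smaller γ (weaker regularization inflation is the greater
  risk). Probabilities are per-binary Platt-calibrated sigmoid scores
  renormalized across classes. When the smallest class has fewer samples
  than the inner fold count, the fold count drops to that class size (with
  a warning); below 2 samples, grid selection is skipped.
* **Random Forest.** T = 500 trees by default, unlimited depth, min leaf 1,
  √d features per split, bootstrap sampling; the ensemble probability is the
  arithmetic mean of per-tree leaf class frequencies. Standardization is
  applied first for interface consistency even though trees are
  scale-invariant.
* **Attention-gated MLP.** Exactly a feature-wise sigmoid gate
  (`A = σ(W_attn F + b_attn)`, `W_attn ∈ R^{d×d}`), elementwise weighting,
  and a linear softmax head — no additional hidden layers. Inputs are
  standardized (same contract as the SVM) for conditioning. Training: joint
  cross-entropy over gate and head, Adam at 1e-3, batch 64, ≤300 epochs,
  early stopping (10% validation split, patience 15), scaled-uniform init,
  seeded; training aborts with a diagnostic on non-finite loss. Softmax uses
  max-subtraction.

Label prediction is the probability argmax with ties broken by the lowest
class index, so outputs are deterministic.

### Soft voting

The fused distribution is stored as the arithmetic *mean* of the K source
rows (so it remains a probability matrix); the argmax is identical to the
sum form. Voters are equally weighted. CSV ingestion aligns permuted class
columns and sample orders by id, renormalizes rows whose sums are off by at
most 1e-3 (absorbing printed-precision rounding) with a warning, and rejects
larger deviations.

### Evaluation

* **Stratification**: within each class, samples are shuffled (seeded) and
  dealt round-robin across folds, starting at fold `class_index mod K` to
  balance overall fold sizes; per-class fold counts differ by at most 1
  (a 42-sample class under K = 5 splits {9,9,8,8,8}).
* **Headline accuracy** is the unweighted mean of fold accuracies; pooled
  accuracy over concatenated test folds is reported alongside.
* **Per-class accuracy** is class recall (confusion diagonal over row sum).
* **AUC** is one-vs-rest per class from the midrank Mann-Whitney statistic,
  equal to the O(n²) pairwise comparison count; classes absent from a test
  set get NaN and are excluded from averages.
* **Paired t-test**: two-sided on fold accuracy differences, df = K−1,
  sample s.d.; all-zero differences give t = 0, p = 1 by convention. Raw
  p-values are reported without multiple-testing correction, matching the
  pairwise-comparison-table convention of the application domain.

## Synthetic data

`generate_synthetic_features` emulates the statistical structure the
pipeline assumes: per-class counts come from largest-remainder apportionment
of a proportion vector (deterministic, exact totals — no multinomial
noise), and each view is `x = centroid_v[class] + ε` with unit Gaussian
noise. Centroids are random directions scaled so the expected pairwise
centroid distance equals `separation` noise-s.d.; a `view_correlation`
parameter mixes a cross-view shared class signal with a view-private one
(at 1.0, equal-dimension views carry identical centroids). Separation 8 is
near-perfectly separable (the parameter-recovery regime); separation 0 has
no class signal at all.

`generate_synthetic_images` renders stylized sperm-like glyphs — an ellipse
head plus a curved, tapering tail drawn anti-aliased (supersampled 4×) on a
white background — whose five shape parameters (head semi-axes, tail length,
tail waviness, neck width) are class-determined with multiplicative Gaussian
jitter of s.d. ∝ 1/separation (clamped at separation ≤ 0.25 so zero
separation yields heavy but bounded jitter). Grayscale is replicated to
three channels.

`simulate_correlated_sources` produces per-classifier probability matrices
with controllable marginal accuracy and pairwise error correlation (a
shared-indicator mixture: with probability ρ all sources reuse one
correct/wrong draw, otherwise they draw independently, so the error
indicator correlation equals ρ). Confidence on the predicted class is
jittered slightly to avoid systematic argmax ties.

What the generators do **not** emulate: staining/color variation, realistic
morphology (the glyphs are caricatures), intra-class shape multimodality,
label noise, and the non-Gaussian, manifold-structured geometry of real CNN
embeddings. Passing parameter-recovery tests therefore shows the pipeline's
machinery is correct under its own assumptions — not that any particular
accuracy transfers to real microscopy data.

## Study-condition problem sizes

The package's self-checks run at desk scale, chosen once as the smallest
sizes at which the phenomena of interest are stable: the 18-class
parameter-recovery run uses n = 3,000 samples with the reference imbalance
profile, three 64-dim views, separation 8, and a two-point SVM grid
({scale} × {1, 10}; the full default grid is unnecessary on cleanly
separable data); the correlated-source voting study uses n = 2,000, three
sources at ~0.7 accuracy, error correlation 0.25, over 20 seeds. At these
sizes the rarest class contributes ~6 samples — deliberately stressing the
small-class paths (inner-CV fold reduction, per-class fold spread).

## Determinism

Every stochastic stage takes an explicit seed; numpy `default_rng` drives
generators and trainers, sklearn estimators receive `random_state`, and the
experiment runner derives per-fold seeds by fixed offsets from the master
seed. Reports (JSON/CSV) contain no timestamps, and dictionary keys are
sorted, so a rerun of `run-all` with the same config and seed is
byte-identical.

## Known limitations

* The SVM's probability calibration (per-binary Platt + renormalization) is
  one of several defensible conventions; calibrated probabilities, not just
  labels, affect soft-voting results.
* `run_experiment`'s reduction path fits the reduction layer once per view
  on a stratified 80% subset rather than refitting inside every CV fold — a
  pragmatic compromise that keeps the grid tractable; the classifiers' own
  cross-validation remains leakage-free with respect to classifier fitting
  and standardization.
* Glyph images are far easier than real microscopy crops; image-pipeline
  tests validate plumbing and moment statistics, not clinical difficulty.
* With extremely rare classes (< K samples) stratified folds necessarily
  miss the class in some folds; affected metrics are flagged NaN rather
  than imputed.
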