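# Methods

This note documents the models, defaults and design choices behind
`multikano`: what each stage assumes, which knobs matter, what the
synthetic data does and does not emulate, and where the numerical edges
are.

## Problem setting

Input is a paired single-cell multi-omics dataset: an RNA cells × genes
count matrix and an ATAC cells × peaks count matrix over the same ordered
cell set, plus per-cell type labels for training. The task is supervised
cell-type annotation: train on labelled cells, predict types for new cells
measured with the same features.

## Preprocessing

Each modality is preprocessed separately, then concatenated per cell.

- **RNA**: per-cell depth normalization to `rna_target_sum` (default 10⁴)
  total counts, `log1p`, then selection of the `n_hvg` (default 3000,
  capped at the number of genes) most variable genes by the dispersion
  statistic var/mean of the log-normalized values. Ties break toward the
  lower feature index so the selection is fully deterministic.
- **ATAC**: counts are binarized (open/closed; configurable), peaks open
  in fewer than `atac_min_cell_fraction` (default 1%) of cells are dropped,
  and the remaining binary matrix is TF-IDF weighted with
  tf = the (binarized) count and idf = log(1 + n_cells / (1 + n_open)).
  This keeps the transform entrywise and exactly reproducible by a
  brute-force formula, which the tests exploit.
- **Concatenation**: each block is independently z-scored per column,
  clamped to ±`clip_value` (default 10), divided by 3 and clamped to
  `squash_to` (default [−1, 1]). The division by 3 maps ±3σ onto the full
  spline-grid domain, so typical values use the whole grid while outliers
  saturate at the boundary rather than leaving the domain.

All statistics fitted from data — the HVG set, peak filter, idf vector and
column scalers — are frozen on the training cells and re-applied verbatim
to test cells. The module contains no randomness, and the fitted state
round-trips through a JSON manifest whose hash is stored with trained
models so feature mismatches are caught at prediction time.

## Augmentation

Rationale: two cells of the same type have near-identical expression and
accessibility programs, so the RNA half of one cell's preprocessed feature
row can be joined to the ATAC half of another same-type cell's row to form
a new, label-preserving training example.

- Donor pairs are **ordered** — (RNA from *a*, ATAC from *b*) differs from
  (RNA from *b*, ATAC from *a*) — and self-pairing is forbidden, so a class
  with n cells offers n(n−1) distinct synthetic cells.
- Default quota ("balance mode"): every class is topped up to the largest
  class size, capped at twice its own size; a singleton class contributes
  nothing. This helps minority types without letting synthetic cells
  dominate. Explicit per-class quotas are available.
- Sampling is seeded and without replacement by default; with a quota at
  or above the pair count, every pair is used exactly once.
- Augmentation runs **inside each training fold, after preprocessing**.
  The CV harness asserts that no donor comes from outside the training
  fold; that assertion failing is a bug, not a warning.

## The KAN classifier

Each edge of the network carries a learnable 1D function

φ(x) = w_b · silu(x) + w_s · Σᵢ cᵢ Bᵢ(x)

with B-spline basis functions Bᵢ of degree k on a uniform extended knot
grid of G intervals over [a, b]; nodes sum their incoming edges with no
further nonlinearity. Defaults: G = 5, k = 3, domain [−1, 1], one hidden
layer of width 64 (architecture [d, 64, K]). The silu base term can be
disabled (`use_base=False`) for a pure-spline variant.

Implementation notes:

- The basis is evaluated by the dense Cox–de Boor recursion over all
  G + 2k intervals, vectorized over the batch; x = b is assigned to the
  last domain interval so the partition of unity closes at the right
  boundary. Points outside [a, b] are evaluated by the same recursion
  (upstream clamping makes them rare).
- The layer forward pass folds w_s into the coefficients and reduces to a
  single GEMM of the flattened basis tensor against the effective weight
  matrix; the backward pass reuses the same flattening for the parameter
  and input gradients (input gradients need dBᵢ/dx, obtained from the
  degree-(k−1) basis by the standard derivative recurrence).
- Grids are fixed at construction; no data-driven grid refinement is
  performed.
- Initialization: spline coefficients ~ N(0, 0.1²), w_s = 1, w_b uniform
  with a fan-in-scaled bound; fully determined by the seed.
- Argmax prediction breaks ties toward the lowest class index.

**MLP baseline.** A ReLU MLP with its hidden width chosen so its parameter
count matches the KAN's within 10% (a KAN edge holds G + k + 2 parameters
vs an MLP edge's 1, so the hidden layer is roughly 10× wider). The
KAN-vs-MLP ablation therefore compares architectures at comparable
capacity.

## Training

Minibatch Adam (lr 10⁻³, weight decay 10⁻⁵ as L2 added to the gradient,
batch 128) on softmax cross-entropy, no early stopping. The default is 60
epochs: on the desk-scale datasets this package targets, the loss plateaus
well before that, and the cross-validation harness repeats training
15+ times, so the default favors a converged-but-economical budget; all of
it is overridable in `TrainConfig`. One RNG stream seeded from
`TrainConfig.seed` drives initialization and epoch shuffles, making
(data, config, seed) → predictions bit-reproducible. A NaN/Inf loss aborts
with a diagnostic rather than continuing silently.

The random-guessing (RG) baseline draws, for each test cell, a uniform
type among the distinct training types; drawing from the empirical label
frequencies instead is available via a flag. Uniform is the default
reading because with balanced classes both coincide, and uniform gives the
cleaner analytic chance level 1/K used by the tests.

## Evaluation

- **Metrics**: accuracy = trace/N; Cohen's κ = (p_o − p_e)/(1 − p_e) with
  the degenerate single-class perfect table defined as κ = 1; macro-F1 as
  the unweighted mean of per-class F1 with 0 for classes where
  precision + recall = 0. All three are cross-checked against independent
  formula and scikit-learn oracles to 10⁻¹².
- **Cross-validation**: stratified folds built by per-class seeded shuffle
  and round-robin assignment (per-class fold sizes differ by ≤ 1). Every
  fold refits preprocessing and augmentation from its training cells only.
- **Exact Wilcoxon signed-rank** (one-sided, paired): zero differences are
  dropped; |differences| are midranked; the null distribution of the
  positive rank sum over all 2ⁿ sign assignments is computed by dynamic
  programming on the doubled-midrank lattice, carried as dyadic
  probabilities (multiplying by 1/2 is exact in binary floating point), so
  n uniformly positive differences give exactly 2⁻ⁿ — for n = 25,
  2.9802 × 10⁻⁸. The DP is used up to n = 50; beyond, a tie-corrected
  normal approximation. The DP is validated against full 2ⁿ enumeration
  for n ≤ 12 and against an independent exact implementation on tie-free
  inputs.
- **Robustness to the number of cell types**: starting from K classes, one
  uniformly chosen class is removed at a time (seeded) and CV re-run, down
  to two classes — K − 2 steps.
- **Differential features (DEGs/DAPs)**: per-feature two-sided
  Mann–Whitney/rank-sum test of the group against the rest, asymptotic
  with tie correction; constant features get p = 1 by convention. Features
  are ranked by ascending p, then descending |difference of group means|,
  then index. Top-k overlap between two rankings is |top_k ∩ top_k| / k.
  At n = 10 cells the normal approximation agrees with exact enumeration
  to within about 0.05 in p, which is the documented tolerance.

## Synthetic data

The generator emulates the *structure* of paired datasets, not any real
tissue:

- K cell types (default 4 balanced types of 150 cells); per type, a
  disjoint signature set in each modality (default 10% of features).
- RNA: gamma–Poisson (negative binomial) counts, Var = μ + φμ² with
  dispersion φ (default 0.5), per-gene base means ~ Gamma(2, 1), per-cell
  library factors ~ LogNormal(0, 0.3); signature genes have their mean
  multiplied by `effect_size` (default 2).
- ATAC: per-peak Bernoulli open/closed (signature peaks 0.4, background
  0.05) times Poisson(1) reads — sparse and near-binary, the qualitative
  character of real scATAC data.
- Optional batch effects: per-batch depth factors
  exp(batch_shift · centred batch index), applied by Poisson resampling so
  counts stay integer; batch_shift = 0 is the exact identity.
- A split-signal variant arranges four types in a 2 × 2 design where RNA
  resolves only one factor and ATAC only the other, giving each single
  modality a 0.5 accuracy ceiling — the cleanest way to demonstrate the
  multi-omics advantage.

Default problem sizes used by the test suite: the standard fixture
(600 cells, 200 genes, 300 peaks) for parameter recovery; 4 × 50 cells for
the split-signal ablation; 4 × 15 cells with effect size 1.5 and dispersion
0.8 for the small-sample augmentation ablation. These were chosen as the
smallest scales at which the phenomena of interest are stable across seeds.

What the generator does **not** emulate: realistic genomic coordinates,
doublets, ambient RNA, trajectory/continuum structure, realistic
gene–peak linkage, or per-type proportions of any real tissue. Passing
tests on this data therefore demonstrate correctness of the pipeline and
qualitative directions (multi-omics > single-omics when signal is split;
augmentation helps at small n), not performance claims about real tissues.

## Numerical choices and degenerate inputs

- All-zero RNA cells stay all-zero (no division by zero); zero-variance
  columns pass through standardization unscaled.
- HVG ties break toward the lower feature index; fold assignment and donor
  sampling are seeded; argmax ties break toward the lowest class index —
  every stochastic or order-dependent choice is pinned.
- Filtering that removes every peak raises an error naming the offending
  threshold.
- Network inputs are clamped to the grid domain upstream; basis values at
  the exact right boundary are defined by closing the last interval.

## Known limitations

- Dense NumPy compute: suitable for desk-scale data (10³–10⁴ cells,
  10³–10⁴ features after selection), not atlas-scale matrices.
- No rejection option for cell types absent from the training set.
- No explicit batch-effect correction; robustness must come from the
  model, which the synthetic batch injector lets you probe but not prove.
- Grid refinement/extension for the splines is intentionally not
  implemented; inputs are bounded by construction instead.
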