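# Methods

## The model

The package aligns two single-cell datasets — possibly from different
technologies with different feature panels — by training two coupled
self-organizing maps (SOMs). Each map is a rectangular `m × n` grid of
nodes (default 10 × 10); node `j` of map 1 carries a codebook vector
`V_j^(1)` in dataset 1's feature space and node `j` of map 2 carries
`V_j^(2)` in dataset 2's space. The grids share their geometry, so node
`j` means "the same place" on both maps.

Training interleaves two kinds of stochastic update. At iteration `t` a
cell `X_i^(1)` is drawn from dataset 1 (and symmetrically `X_i^(2)` from
dataset 2):

* **independent update** — the best-matching unit (BMU) `b` is the node
  whose codebook is nearest (Euclidean) to the cell; every node within
  grid distance `ε_t` of `b` moves toward the cell:

      V_j ← V_j + δ_i · α_t · (X_i − V_j)

* **joint update** — the cell's matched partner `X̃_i^(2)` from the
  *other* dataset (see matching below) pulls the *other* map's codebooks
  at the *same* node set toward itself, with the same weight `δ_i · α_t`.

The joint step is the coupling: wherever dataset 1 places a population on
the grid, the matched dataset 2 cells drag map 2's codebooks to the same
grid region, so related populations end up on overlapping nodes even
though the two maps live in different feature spaces.

### Matching and the weight δ

The matching is computed once, before training, on the *shared features*
only — the columns the user declares to correspond across the datasets
(overlapping protein markers, common highly variable genes mapped through
their own PCA, ...). Two modes:

* **correlation** (default): each cell is matched to the cell of the
  other dataset with the highest Pearson correlation across shared
  features; `δ` is that correlation, clamped to `[0, 1]`. The clamp is a
  deliberate choice: `δ` multiplies the learning rate, and a negative
  value would push codebooks *away* from data. `allow_negative_delta`
  restores the raw correlation for comparison.
* **binary** (cytometry): each shared marker is binarized at a
  two-segment step threshold (below); cells are matched by the fraction
  of markers that agree (both positive or both negative), which is also
  `δ`. This mirrors how manual gating reasons about positivity.

A constant cell (zero variance over shared features) has no defined
correlation; it gets `δ = 0` (it neither drives nor receives joint
updates) and a warning.

### Step thresholds

The binary mode needs a per-marker threshold separating "negative" from
"positive". We fit a rising two-segment constant function to the sorted
values: over every split point the two segments are fitted by their
means, the split minimizing total squared error wins (ties → smallest
split), and the threshold is the midpoint of the two segment means.
Implemented with prefix sums, O(L) per marker after sorting; a constant
marker admits no step and is dropped from both panels (positional
correspondence must be preserved).

### Schedules

* learning rate: `α_t = α0 + (α_final − α0) · t/(T−1)`, defaults
  `α0 = 0.9`, `α_final = 0.01` (the final value is a choice; only the
  linear decay is prescribed).
* neighborhood radius: `ε_t = ε0 · (1 − t/(T−1))`, decaying to 0; once
  `ε_t < 1` only the BMU itself is updated. Default
  `ε0 = ⌈2(max(m,n)−1)/3⌉` (6 on a 10 × 10 grid), so the initial
  neighborhood spans roughly two thirds of the grid. Both decays are
  per-iteration.
* iteration count: `T = epochs · max(n1, n2)` with `epochs = 3` by
  default. Sampling uses a fresh seeded permutation of each dataset per
  epoch (so every cell is used exactly `epochs` times); the smaller
  dataset's permutation is recycled. Pure i.i.d. draws are available via
  `sampling="iid"`.

### Numerical choices

* The update is computed as `(1 − δα)·V + δα·x`. Algebraically identical
  to `V + δα(x − V)`, but the convex arrangement makes a full step
  (`δα = 1`) land on `x` exactly and a zero step leave `V` exactly
  unchanged, and it makes every update a convex combination: codebooks
  provably never leave the bounding box of data and initialization.
* BMU search compares squared Euclidean distances with a plain row-wise
  reduction and breaks ties by the lowest node index. Late in training,
  codebook rows inside one neighborhood converge to near-equality, so a
  reproducible reduction order and an explicit tie rule matter for
  bit-level determinism.
* Grid neighborhoods use Euclidean distance on integer (row, col)
  coordinates with a hard cutoff (no Gaussian kernel), the common choice
  for rectangular SOMs.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` children (map initialization, the two draw
  orders, downsampling), so every stage is bit-reproducible.

### Density-dependent downsampling

Datasets above the training cap (default 10 000 cells) are subsampled
with keep-probability inversely proportional to local density, so rare
populations survive the cap. Local density is the number of cells within
a kernel radius of 5 × the median nearest-neighbor distance; cells below
the 1st percentile of density are discarded as outliers; the target
density `TD` is the largest value with `Σ min(1, TD/d_i) ≤ target`
(bisection), and cell `i` is kept with probability `min(1, TD/d_i)`.
The 5× multiplier and the 1 % outlier percentile are conventions borrowed
from the SPADE-style scheme and are configurable (`outlier_percentile=0`
disables outlier removal). With downsampling skipped, a plain uniform
subsample enforces the cap instead. The matching must be computed on the
downsampled rows (downsample → match → train); final node assignment
always uses the full datasets.

### Post-training products

* **assignment**: every cell of each full dataset goes to its nearest
  node of its own map.
* **mode maps**: per-node majority label; ties go to the
  lexicographically smallest label, empty nodes are marked explicitly.
* **superposition clusters**: Ward clustering (Euclidean) of the
  concatenated codebooks `[V1 | V2]`, cut at `K = max(m, n)` clusters by
  default, relabeled by first-occurring node index.
* **label transfer**: query cells inherit the majority label of their
  node from the annotated reference; a query landing on a node the
  reference never occupied takes the nearest (grid-distance) non-empty
  node's label and is flagged imputed. The fallback is ours — the
  prediction function must be total.

### Metrics

* **node purity** = fraction of cells (pooled over both datasets) whose
  label equals their node's own-dataset majority — clustering quality.
* **matching score** = fraction of cells whose label equals the *other*
  dataset's majority at the same node — alignment quality. Cells on
  nodes the other dataset never occupies stay in the denominator and
  cannot match; unlabeled cells are excluded with a warning.
* **alignment RMSE** = RMSE between the two codebook sets over
  shared-feature pairs, i.e. how literally node `j` encodes the same
  shared profile on both maps.
* **average KL divergence** = mean KL (natural log, unweighted over
  non-empty groups) of each node's batch-label distribution from the
  global one; 0 means perfectly mixed batches. Base and weighting are
  conventions of this package.

## The synthetic generator

`generate_paired` draws `k` cluster centers in the shared-feature space
with pairwise separation ≥ `cluster_sep · noise_sd` (rejection sampling),
adds per-dataset private-feature centers, and emits Gaussian cells around
them. Dataset 2 sees the shared coordinates through a per-feature affine
map `a·x + b` with `a ~ 1 + N(0, s)`, `b ~ N(0, s)`
(`s = shared_distortion`), emulating cross-technology scale and offset
differences; optionally one cluster is omitted from dataset 2 (the
missing-population scenario). Defaults — 5 clusters, separation 6 noise
SDs, distortion 0.05, unit noise — describe two clean, well-separated
views of the same biology.

What it deliberately does **not** emulate: count noise (negative
binomial, dropout), library-size variation, nonlinear batch effects,
continuous trajectories, or unbalanced feature panels beyond the
private-feature blocks. Values stand in for data *after*
variance-stabilizing preprocessing. Passing tests on this generator
therefore demonstrate that the machinery is correct and that alignment
degrades gracefully with distortion — not that the method conquers any
particular real dataset.

## Problem sizes used in the checks

The test suite and the acceptance script run the full pipeline at 5
clusters × 500 cells per cluster per dataset (5 000 cells total, 12
features each) on a 10 × 10 grid with 3 epochs, the downsampling check at
10 000 cells, and the SOM-equivalence check at 2 000 cells — sizes chosen
so the whole suite completes in well under a minute per scenario while
still exercising every stage at realistic per-cluster depth.

## Known limitations

* Exactly two datasets; no multi-way alignment.
* The matching is a hard argmax per cell (no soft or many-to-many
  matches) and is O(n1 · n2) in time (blocked in memory) — fine at the
  10 k training cap, not for raw atlases.
* Shared features must be declared by the user; the method does not
  discover correspondences.
* Batch-SOM (deterministic) training and hexagonal/toroidal grids are
  out of scope.
* The number of PCA components is user-supplied; no permutation test for
  significant components is included.
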