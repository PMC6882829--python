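# Methods

## Problem and model

t-SNE embeds n high-dimensional points x_i into 2-D coordinates y_i by
matching two similarity distributions. In the input space, each point i
defines a Gaussian conditional distribution over its neighbours,

    p_{j|i} ∝ exp(−‖x_i − x_j‖² / 2σ_i²),

with the bandwidth σ_i calibrated per point so that the distribution's
perplexity 2^{H(p_{·|i})} (base-2 entropy H, i.e. the effective neighbour
count) equals a user-chosen target 𝒫. Joint similarities are the symmetrised

    p_ij = (p_{i|j} + p_{j|i}) / (2n),  Σ_ij p_ij = 1.

In the embedding the kernel is the Cauchy (t-distribution with one degree of
freedom) form q_ij = w_ij / Z with w_ij = 1/(1 + ‖y_i − y_j‖²) and
Z = Σ_{k≠l} w_kl. The loss is the KL divergence Σ p_ij log(p_ij / q_ij),
which splits into an attractive force between each point and its neighbours
(carrying p_ij) and a global repulsion between all pairs.

The package's purpose is not t-SNE per se but a protocol that makes its
output preserve structure at all three scales of hierarchically organised
single-cell data:

* **multi-scale similarities** — averaging the conditional distributions
  calibrated at perplexity 30 and at n/100 (truncated to an integer)
  whenever n ≥ 6000, so local and mesoscopic neighbourhoods both carry
  attraction;
* **PCA initialisation** — starting from the first two principal-component
  scores rescaled to sd(PC1) = 1e-4, which injects the macroscopic
  arrangement and makes the run deterministic;
* **high learning rate** — η = max(200, n/12), preventing the poorly
  converged, fragmented layouts the default η = 200 produces at large n;
* for very large data sets, **exaggeration** (keeping the attractive term
  multiplied by α ≈ 4 after the early phase) and **downsampling-based
  initialisation** (embed a 25,000-cell subsample with the standard
  protocol, place every remaining cell at the coordinate-wise median of its
  k = 10 Euclidean nearest subsample neighbours in PC space, rescale, and
  use that to initialise a perplexity-30 full run).

## Optimiser

Adaptive gradient descent with momentum, exactly the scheme of the classical
implementations: per-coordinate gains start at 1, grow by +0.2 when the
gradient disagrees in sign with the running update, shrink ×0.8 when it
agrees, floored at 0.01; momentum 0.5 for the first 250 iterations and 0.8
after; early exaggeration α = 12 for the first 250 of 1000 iterations (when
a recipe is run with fewer iterations, the early phase is min(250,
n_iter/4)). Initial coordinates must be ~1e-4 in magnitude; the optimiser
warns otherwise.

**Gradient convention.** The returned gradient is

    α · Σ_j p_ij w_ij (y_i − y_j) − (1/Z) Σ_{j≠i} w_ij² (y_i − y_j),

which is exactly 1/4 of the calculus gradient of the (exaggerated) KL loss.
The classical factor 4 is folded into the learning rate, as in the
Barnes-Hut/FIt-SNE lineage, so that η = n/12 here means what the protocol
intends. Implementations that keep the factor (e.g. scikit-learn) need η/4
for the same trajectory; the oracle test therefore checks 4·gradient against
numerical differentiation of the loss.

**Attraction** is computed over the sparse support of p_ij: each conditional
distribution is truncated to the ⌈3𝒫⌉ exact nearest neighbours (for a
multi-scale combination, 3·max 𝒫 neighbours shared by all scales so the
averaged rows still sum to 1). Neighbour search is exact brute-force by
default and is the oracle; an approximate backend can be injected as a
callable returning (squared distances, indices).

**Repulsion** is exact (dense O(n²)) for n ≤ 5000 and Barnes-Hut above: a
quadtree is rebuilt every iteration, and a cell of
side s at distance d from the target point is summarised by its centre of
mass when s/d < θ (default θ = 0.5; θ = 0 recovers the exact sum to machine
precision). The same traversal accumulates the normaliser Z. Near-duplicate
points share a leaf bucket below depth 48. Accuracy at θ = 0.5 on 500
scattered points: the force-field approximation error is ≈ 2% (mean
per-point error relative to the rms dense force; aggregate Frobenius ratio
similar), with Z within 1%. Two caveats on pointwise statements: the ratio
‖F_bh − F_exact‖/‖F_exact‖ is ill-conditioned for points whose net repulsion
nearly cancels (a point with force norm 0.04 in a layout whose median force
is 1.5 showed a ratio of 0.8 at an absolute error of 0.04), and even
relative to the rms force the single worst point typically sits at 5-8% —
accuracy statements therefore describe the field (mean/aggregate), not the
worst point.

**Perplexity calibration** bisects on log σ² (bracket [1e-20, 1e20], at most
200 iterations) until the achieved perplexity is within 1e-5 of the target.
Degenerate rows — e.g. all candidate distances equal, pinning the perplexity
at the candidate count — are reported as errors naming the row. The uniform
limit (target = number of candidates) is reachable within tolerance.

## Preprocessing

Fixed order: feature selection on **raw** counts → depth normalisation of
the selected genes → log2(x+1) → optional standardisation → PCA.

* Depth normalisation: read counts to counts-per-million; UMI counts to the
  median per-cell depth (a CPM scale would distort the subsequent log for
  shallow UMI data).
* Feature selection is dropout-based: per gene, the near-zero fraction
  d_g = (1/n) Σ_i I(X_ig ≤ t) and the mean log2 expression m_g over counts
  above t, with t = 0 for UMI and t = 32 for read counts (exposed as a
  flag) and genes expressed above t in fewer than n_min = 10 cells
  discarded (the same t is used for this filter). A gene is selected when
  d_g > exp[−a(m_g − b)] + 0.02 with steepness a = 1.5 (a = 1 suits
  broader dropout distributions); b is found by binary search so that
  exactly M genes qualify, exploiting the monotone non-increasing count.
  The search stops at count = M or bracket width 1e-10, preferring the
  smallest such b; if ties make M unreachable it returns the nearest
  achievable count with a warning.
* Standardisation is off by default (log counts are already on a common
  scale and Euclidean distance after log approximates a count-model
  likelihood); a flag enables it. arsinh(x/5) is available as an
  alternative transform.
* PCA uses an economy SVD of the centred matrix, keeps 50 components, and
  fixes each component's sign so its loadings sum to a nonnegative value —
  this pins the otherwise arbitrary orientation and makes PCA
  initialisation reproducible. The significance-testing variant for picking
  the number of PCs is deliberately not implemented; 50 is fixed.

## Quality metrics

* **KNN** (micro): mean fraction of each point's k = 10 exact nearest
  neighbours in the input representation that remain among its k nearest in
  the embedding; self excluded; distance ties broken by point index.
* **KNC** (meso): same preservation for the k nearest class means, averaged
  over classes; k = 4 on the 15-type benchmark, 10 by default.
* **CPD** (macro): Spearman correlation (average-rank ties) between
  high-dimensional and embedded pairwise distances over a seeded
  1000-point subsample without replacement — 499,500 pairs.

"High-dimensional" means the matrix handed to the embedder (the 50-PC
scores in the standard pipeline; the raw 50-D coordinates for the synthetic
benchmark). All three metrics are invariant to rigid transforms and uniform
rescaling of either space.

## Atlas mapping

A query cell is positioned at the coordinate-wise median embedding location
of its k = 10 nearest reference cells under correlation distance
(1 − Pearson across the log2-transformed shared genes; gene matching is by
ID intersection, and correlation distance is preferred here for robustness
to between-protocol batch effects). Coordinate-wise median — not geometric
median — is used deliberately: it is what the protocol specifies and is
robust to ⌊(k−1)/2⌋ corrupted neighbours per axis. Leave-one-out validation
re-positions reference cells with themselves excluded and reports Euclidean
displacements. Uncertainty comes from B = 100 bootstrap resamples of the L
shared genes (with replacement): the 5% of bootstrap positions farthest from
the original mapping are discarded and the convex hull of the remaining 95%
is the confidence region; collinear bootstrap clouds degenerate to a
segment and are returned as such. An optional force-based refinement of
mapped positions was considered and not implemented — the plain median
positioning is accurate enough on separable references, and refinement adds
an optimisation with its own failure modes. The same positioning, rescaled
to the sd(first coordinate) = 1e-4 initialisation convention, provides
aligned initialisations for embedding a related data set on top of a
reference layout. (Downsampling-based initialisation in the large-data
recipe uses Euclidean distance in PC space instead — no batch effect exists
between a sample and its own subsample.)

## Synthetic benchmark

The generator draws from a mixture of fifteen 50-dimensional spherical
unit-variance Gaussians: three classes of five types. Class means are
shifted by 20 along distinct standard basis vectors e_0..e_2; type means
within every class by 4 (the 2000-points-per-type class) or 10 (the 1000-
and 100-per-type classes) along e_3..e_7. Using fixed basis vectors (rather
than random orthonormal directions) is distributionally equivalent up to a
rotation and keeps runs reproducible; type directions are orthogonal to all
class directions, and reusing e_3..e_7 across classes is harmless because
classes are already 20√2 apart. Rows are grouped by class then type, with
an optional shuffle (off by default — embeddings are order-insensitive and
unshuffled files diff cleanly). Class means land 20√2 ≈ 28.3 apart and
within-class type means s√2 apart.

What the benchmark emulates: the hierarchical class/type geometry typical
of single-cell data, at realistic scale (n = 15,500). What it does not:
count noise, dropout, library-size variation, batch effects, or unequal
cluster anisotropy — so green tests here demonstrate the protocol's
geometric behaviour, not robustness to the sampling noise of real scRNA-seq
counts (the preprocessing modules are tested on synthetic counts
separately).

## Numerical and design choices

* Default seed 42 everywhere a seed exists; seeded runs are bit-reproducible
  on a platform, and PCA-initialised recipes are deterministic outright.
* The n/100 perplexity component is truncated, not rounded; multi-scale
  averaging happens on conditional distributions *before* symmetrisation
  (the closed-form two-kernel approximation is documented but not used as
  the implementation).
* Multi-scale activation at n ≥ 6000 operationalises "n/100 ≫ 30"
  (n/100 ≥ 60, i.e. double the base perplexity).
* Subsampling in the large recipe is uniform without replacement, seeded.
* Early exaggeration stays active under PCA/custom initialisation.
* Degenerate inputs: zero-depth cells, zero-variance query profiles,
  constant PC1, unreachable perplexities and diverging optimisations all
  raise errors naming the offending entity; constant columns in
  standardisation and unreachable feature-selection counts warn instead.
* Embeddings may be rigidly rotated/flipped for display but never stretched
  per-axis; no such post-processing is applied by the library.

## Problem sizes in the test suite

The acceptance-style checks run the full benchmark (n = 15,500) through the
default run, the full protocol, and a single-scale perplexity-155 run, and
the large-data recipe at n = 20,000 with a 2,000-point subsample — sizes
chosen so the whole suite completes comfortably on a single CPU while still
exercising the Barnes-Hut path far above the exact-gradient threshold. The
per-module tests use 10-600 points where oracles (dense gradients, grid
scans, hand enumeration) are exact.

## Known limitations

* The repulsion approximation is Barnes-Hut (O(n log n)); the FFT
  interpolation scheme used for million-cell runs is out of scope, so
  multi-million-point embeddings are slow here.
* Only 2-D embeddings; the low-dimensional kernel's degrees of freedom are
  fixed at ν = 1.
* Default-parameter runs (random initialisation) have seed-dependent
  meso/macro structure — that is the failure mode the protocol exists to
  fix, but it also means any single-run KNC/CPD value for the naive
  baseline carries substantial run-to-run spread; comparisons should
  average over seeds, and reported baseline values from different t-SNE
  implementations can differ by more than the seed spread.
* Very small or very isolated rare clusters can be mis-placed by large
  perplexities and PCA initialisation alike; an MDS plot of cluster means
  is the recommended companion diagnostic.
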