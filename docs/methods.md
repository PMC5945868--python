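# Methods

## Problem and model

`gwcparc` parcellates a single subject's resting-state fMRI volume into K
spatially coherent, functionally homogeneous clusters. The pipeline has two
stages.

**Stage 1 — supervoxels.** SLIC (local k-means) is run directly on the
voxel time series. Each voxel i carries its z-scored time course v_i and
its voxel-index coordinates u_i; the unified distance is

    d(i, j) = ||v_i − v_j||² / m²  +  ||u_i − u_j||² / S²,

with S = (N0 / n_supervoxels)^(1/3) the expected supervoxel edge length and
m the functional normalizer. Seeds start on a regular grid of spacing S
restricted to the mask (out-of-mask grid points snap to the nearest in-mask
voxel); each iteration assigns voxels within a 2S-wide window of each seed
and recomputes seed centroids and mean series. After the iterations, any
label fragment that is not 26-connected to its label's largest component is
merged into the adjacent label sharing the longest boundary. Z-scoring the
time courses makes ||v_i − v_j||² equal 2T(1 − r_ij), an affine function of
the Pearson correlation, which aligns the SLIC distance with the
correlation-based evaluation metrics. Whether to standardize before the
unified distance is a genuinely open choice; we standardize, and this should
be revisited before any real-data replication.

**Stage 2 — graph-without-cut.** N supervoxels are described by centroid
coordinates X (3×N) and M = 3 feature matrices: the mean z-scored time
course (T×N), a 12-bin intensity histogram of the temporal-mean image, and
a 10-bin histogram of rotation-invariant 6-neighbor 3D local binary
patterns of the same image. The method learns an affinity graph
S ∈ R^{N×N} (columns on the probability simplex, at most k nonzeros, zero
diagonal) and simplex feature weights α by minimizing

    Σ_ij ||x_i − x_j||² s_ij + λ Σ_m α_m Σ_ij ||y_i^(m) − y_j^(m)||² s_ij
      + μ Σ_ij ||z_i − z_j||² s_ij + β ||S||_F² + βγ ||α||²,

subject to Z'Z = I with Z ∈ R^{N×K}. All pairwise-distance terms enter as
graphs normalized by their own maximum and then squared (normalizing the
raw coordinates or features instead degrades clustering). Because the K
smallest Laplacian eigenvalues of S sum to tr(Z'LZ) at the optimum, a large
μ forces that sum toward zero, i.e. forces S to have exactly K connected
components — the partition is read off the graph itself rather than cut
out of it afterwards.

Block updates, each exactly optimal for its subproblem:

* **Z**: eigenvectors of the K smallest eigenvalues of L = D − (S + S')/2.
* **S**: per column i, minimize p_i's + β s's on the simplex where p_i is a
  column of the cost matrix P (weighted sum of squared normalized graphs).
  β is chosen implicitly so that the solution has exactly k nonzeros,
  giving the closed form s_(j) = (p_(k+1) − p_(j)) / (k p_(k+1) − Σ_{h≤k}
  p_(h)) on the k cheapest costs, β = (k p_(k+1) − Σ p_(h)) / 2. Ties at
  the k-th cost break toward the lower index; if the k+1 cheapest costs are
  all equal the column degenerates to uniform 1/k with β = 0. The self
  affinity is pinned to 0 (a zero self-cost would absorb all mass).
* **α**: the simplex projection of −λq/(2β̄γ), where q_m is the Hadamard
  contraction of S with the m-th squared feature graph and β̄ averages the
  per-column β values from the latest S-update (degenerate zero-β columns
  excluded; if β̄ ≤ 0, α is kept and a warning logged).

α starts uniform at 1/M; S is initialized from the cost matrix without the
μ-term (there is no Z yet). Iteration stops when the relative Frobenius
change of S drops below `tol` (1e-4) or after `max_iter` (100) rounds. If
the converged graph has exactly K components they are the clusters;
otherwise normalized-cut spectral clustering with K clusters is applied to
(S + S')/2. Cluster labels are then broadcast from supervoxels to voxels.

## Parameters

| parameter | default | meaning |
|---|---|---|
| n_supervoxels | 1000 | building-block count for whole-brain grids (the phantom experiments use 120 on a 4800-voxel grid, preserving the ~1:10 cluster:supervoxel ratio) |
| m | 10 | SLIC functional normalizer; balances z-scored functional distance against spatial distance (40 makes the result essentially geometric) |
| K | — | initialized (and, via the rank constraint, actual) cluster number |
| λ | 0.1 | feature-term weight; small values keep the spatial term strong enough to preserve contiguity |
| γ | 1 | α-regularization; results are insensitive over several orders of magnitude |
| μ | 1e4 | rank-constraint weight; "sufficiently large" constant |
| k | auto | column sparsity of S, estimated as the rounded mean number of 26-connected supervoxel neighbors |
| max_iter / tol | 100 / 1e-4 | outer-loop control |

**Choosing k.** The adjacency estimate reproduces the original operating
value (nine) on brain-shaped masks, but on a solid box it rises to ~13
because every interior supervoxel touches more neighbors. Since every
column of S carries k nonzeros, a connected component of the learned graph
must contain more than k supervoxels: k must stay below the smallest
expected cluster size or small clusters are forced to absorb foreign edges
and merge. The phantom experiments therefore run at k = 9, the value used
in the original whole-brain experiments; when in doubt choose
k < N/K.

## Numerical choices

* **Numerical zeros in S.** In exact arithmetic the rank mechanism zeroes
  cross-component affinities. In floating point, near-tied huge costs
  (dominated by the μ-term) leave residues of order 1e-8..1e-6, while
  genuine affinities are ~1/k ≈ 0.1. Component counting treats entries
  below 1e-4 — 0.01 % of a column's unit mass — as absent. Without this
  tolerance "exactly K components" would be a measure-zero event.
* **Eigenvector indeterminacy.** Z enters only through pairwise row
  distances, which are invariant to rotations within an eigenspace; for
  repeated eigenvalues the deterministic LAPACK output is used as-is
  (a reproducibility caveat across BLAS builds, not within one).
* **LBP conventions.** Face neighbors are thresholded with ≥ (ties encode
  1); out-of-mask and out-of-grid neighbors encode 0. The 64 patterns are
  grouped by orbits of the 24 proper cube rotations acting on the six face
  directions — the only grouping that yields exactly 10 classes (Burnside:
  (1/24) Σ_g 2^{cycles(g)} = 10). Orbits are indexed by ascending minimal
  pattern integer.
* **"Mean intensity".** Interpreted as the supervoxel's mean z-scored time
  course (d₁ = T); the histogram and LBP features are computed on the
  temporal-mean 3D image, since they need a scalar image and a purely
  structural mean-intensity reading would discard the functional signal.
  These are explicit assumptions.
* **Degenerate inputs.** Constant images produce one-hot histograms;
  all-zero distance graphs pass normalization unchanged; constant time
  courses z-score to zero vectors and contribute zero correlation.
* **k-estimation rounding** is round-half-to-even.
* **Ncut engine.** Symmetric normalization D^{-1/2} W D^{-1/2}, top-K
  eigenvectors (deterministic Lanczos start vector; dense solver below
  N = 200), row-normalized embedding, seeded k-means discretization
  (simpler and deterministic, a deviation from rotation-based multiclass
  discretization). Negative weights (possible under the correlation weight
  scheme) are clipped at zero before embedding. Disconnected graphs get
  clusters allocated to components proportionally to size.
* **Gaussian-weight medians** (σ_v, σ_u) use the exact pairwise median up
  to 1e6 pairs and a seeded uniform subsample beyond that.

## Evaluation metrics

* **Spatial discontiguity index** — within-cluster 26-connected components
  are counted; the index is the excess over the cluster count.
* **Functional homogeneity** — mean Pearson correlation over ordered
  distinct voxel pairs within a cluster, averaged unweighted over clusters
  with ≥ 2 voxels (singletons omitted and reported). Computed in O(N·T)
  via ||Σ z_i||² − Σ ||z_i||² on unit-norm demeaned series; the identity
  is unit-tested against the explicit double loop. Cross-subject
  homogeneity evaluates one subject's atlas on held-out subjects' data and
  averages.
* **Dice reproducibility** — overlap of the same-cluster voxel-pair sets
  (adjacency matrices with diagonal included) of two atlases, computed via
  the contingency-table identity 2Σn_uv²/(Σn_u·² + Σn_·v²) to avoid
  materializing N0×N0 matrices; equivalence with the explicit adjacency
  form is unit-tested. A 36-subject cohort offers 630 pairs; sampling a
  subset of pairs is exposed as a harness concern with a seed.

## Null models

To test whether an approach encodes more than spatial geometry, each
approach is re-run on randomized data with identical parameters: the
supervoxel-based approaches on spatially permuted time series (whole
courses re-assigned to random in-mask voxels, preserving each course), the
normalized-cut baseline on an edge-permuted weight matrix (upper-triangle
values uniformly re-placed, symmetrized, diagonal kept). Homogeneity of
null parcellations is always evaluated on the original volume — two random
datasets share no similarity, so evaluating on the null data itself would
trivially give ~0.

## What the phantom does and does not emulate

The generator plants K_true contiguous parcels by nearest-seed growth from
uniform random in-mask seeds (ties to the lower parcel id) on a box or
ellipsoid mask, assigns each parcel an i.i.d. standard-normal latent course
(optionally moving-average smoothed), and adds i.i.d. Gaussian voxel noise
of s.d. 1/snr. This captures what the method consumes — a correlation
structure organized into contiguous spatial units — but not hemodynamic
autocorrelation, physiological noise, spatial noise correlation from
smoothing, inter-subject variability, or realistic parcel size
distributions (Voronoi cells from uniform seeds are heavily skewed, which
is in fact a harder regime for the rank constraint than equal-size units).
Passing phantom tests therefore demonstrates algorithmic correctness and
the intended qualitative orderings, not real-data performance.

Default study conditions for the phantom experiments: 20×20×12 box
(N0 = 4800), K_true = 8, T = 60, snr = 8, 120 target supervoxels, K = 8,
k = 9 — sized so a full pipeline run takes seconds while preserving the
supervoxel-per-cluster ratio of the whole-brain setting.

## Known limitations

* The exact-K guarantee is empirical here, and requires k below the
  smallest cluster size; with skewed cluster sizes and auto-estimated k it
  degrades gracefully to "Ncut on the learned graph".
* The α weights respond weakly to feature quality when μ dominates β̄
  (large β̄ shrinks the projection argument toward uniform).
* Very large initialized K (beyond ~40 % of the supervoxel count) leaves
  few supervoxels per cluster and the actual cluster number falls below K.
* No fMRI preprocessing is included; inputs are assumed preprocessed and
  already on a common grid. Voxel-index units are used for all distances
  (on a 4 mm isotropic grid they are proportional to mm); the "≤ 3"
  radius of the constrained correlation weight is likewise in voxel units.
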