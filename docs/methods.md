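# Methods

## Model

Classical (Torgerson) MDS treats a dissimilarity matrix `D = [d_ij]` as if
its entries were Euclidean distances and recovers coordinates from the
implied inner products. With `J = I − n⁻¹·1` (the centering matrix), the
Gram matrix is `B = −½ J D² J`, where `D²` squares entries elementwise.
If `(λ_k, e_k)` are the `m` algebraically largest eigenpairs of `B`, the
coordinates are `X = [e_1√λ_1, …, e_m√λ_m]`. When `D` is exactly the
distance matrix of points in `ℝ^m`, `B` is positive semidefinite of rank
at most `m` and the construction returns those points up to rotation,
reflection and translation; otherwise the top-`m` eigenspace is the best
rank-`m` inner-product approximation in the least-squares sense.

The double centering is implemented by subtracting row and column means
and adding the grand mean of `D²`, which is algebraically identical to
forming `J` but O(n²) in time and avoids materializing two extra `n × n`
matrices. Eigenpairs come from `scipy.linalg.eigh` restricted to the top
`m` indices.

## Divide-and-conquer approximation

For `n` above the memory budget the objects are randomly permuted and cut
into `p` contiguous chunks of size `⌈n/p⌉` or `⌊n/p⌋` (larger chunks
first); the induced principal submatrices are the diagonal blocks
`D_1 … D_p`. Each block is embedded exactly. From each subset `s` anchors
are sampled, pooled into the `(sp) × (sp)` matrix `M_align`, and `M_align`
is itself embedded at the same dimensionality `m`, giving the common frame
`mMDS`. For every block the anchor rows of the block embedding
(`subdMDS_i`) and of `mMDS` (`mMDS_i`) are paired, a least-squares
transform from the former onto the latter is fitted, applied to the whole
block, and the transformed blocks are concatenated, restoring the original
object order.

**Affine vs. linear alignment.** Each block embedding is centered on its
own subset centroid, while the anchor embedding is centered on the pooled
anchor centroid; these centroids differ, so a purely linear map between
the two frames cannot absorb the offset. The alignment is therefore
affine by default (the source anchor matrix is augmented with a constant
column so a translation is fitted jointly), which restores exact recovery
on embeddable data. A `linear_only` switch fits the unaugmented linear
map for users who want the strictly linear formulation. The solver is
`numpy.linalg.lstsq`, which returns the minimum-norm solution under rank
deficiency; per-block RMS residuals are recorded in the run metadata, and
`solve_alignment` can warn when a residual exceeds a caller-set threshold.

**Exactness.** When `D` comes from points in `ℝ^m` and each anchor set is
affinely non-degenerate (`s ≥ m+1`, anchors spanning), every block frame
and the anchor frame are rigid images of the same configuration, the
affine fit recovers the change of frame exactly, and the stitched
embedding reproduces all `n(n−1)/2` distances to numerical tolerance
(tested at `1e-6`; the one-shot path at `1e-8`).

## Sampling strategies

*Random* is uniform sampling without replacement. *MaxMin* is greedy
farthest-point selection: the first anchor is a seeded uniform draw
(standard landmark-selection practice; the choice is otherwise
unconstrained), and each later anchor is the unused subset member whose
minimum dissimilarity to the chosen anchors is largest, ties broken toward
the smallest global index so runs are bit-reproducible. MaxMin spreads
anchors across the extent of a block, which matters when the distance
distribution is skewed or highly dispersed and a uniform draw may miss
outlying regions.

## Planning and the memory budget

The mode toggle is driven by an explicit, user-facing object cap
`max_objects` (default 5000) rather than any hardware probing:
`n ≤ max_objects`
runs one-shot, otherwise `p` starts at `⌈n/max_objects⌉` and grows until
both the block size `⌈n/p⌉` and the pooled anchor count `s·p` fit the cap,
with `s = min(default_s, ⌊n/p⌋)` and `default_s = 100`, the
anchors-per-subset setting used for genome-scale matrices. Explicit
`p`/`s` overrides win over auto-derivation and force divide-and-conquer.
One user seed drives both partitioning and sampling through independent
`SeedSequence` spawn-key streams, so switching the sampling strategy does
not change the partition.

## Evaluation metrics

Accuracy of an approximate embedding against a reference is the Pearson
correlation of the two all-pairs Euclidean distance vectors (pairs in
lexicographic `i < j` order, rows re-aligned by object id first); it is 1
exactly when the two embeddings differ by a rigid transform. For `n`
large enough that the `n(n−1)/2` vector is unwieldy, a seeded subsample of
pairs can be used (off by default; agreement with the exhaustive value is
within 0.02 at `n = 1000` in the test suite). Distance-distribution shape
is summarized by `PMSC = 3(mean − median)/sd` and `CV = sd/mean`. Both use
the sample standard deviation (`ddof = 1`); with thousands of pairs the
population/sample distinction is negligible, and the sample convention is
the safer default at small `n`.

## Synthetic data

The generator produces the three regimes the method is exercised on:

* **embeddable point clouds** — standard-normal points in `latent_dim`
  dimensions with their exact distance matrix; the fixture for
  exact-recovery checks.
* **clustered mixtures** — `n_clusters` isotropic Gaussian clusters in
  `ambient_dim` dimensions. Centers are drawn from `N(0, (5σ)² I)` with
  `σ` the within-cluster spread: five-fold separation gives clearly
  distinct clusters, a stand-in for clustered expression profiles.
  Defaults (`n = 2000`, `ambient_dim = 20`, 5 clusters, `σ = 1`) define
  the clustered benchmark used by the acceptance script.
* **skewed data** — a `skew ≥ 0` parameter remaps the first coordinate
  through `x ↦ (exp(skew·z) − 1)/skew` of its standardized value `z`, a
  monotone warp that stretches the right tail. Only its monotone effect on
  the distance-distribution PMSC is contracted (verified over 20 seeds in
  the tests); the particular warp is an implementation choice.

The generator emulates cluster structure, exact embeddability and
distance-distribution shape; it does not model platform noise,
missingness, or the heavy-tailed intensity distributions of real
microarray data, so passing tests demonstrate correctness of the
algorithms on these structural regimes, not performance on any particular
real dataset. Euclidean distance is the only built-in dissimilarity — it
is the metric classical MDS models; other dissimilarities can be supplied
directly as a matrix.

## Numerical choices and degenerate inputs

* All numerics are double precision.
* Input matrices must be symmetric within a relative `1e-8`; below that
  they are symmetrized as `(D + Dᵀ)/2`, above they are rejected naming the
  worst entry. Diagonals must be zero; negative entries are rejected.
* Negative eigenvalues among the top `m` (non-Euclidean input) are clamped
  to zero — the coordinate column becomes zero — with a warning; if no
  top-`m` eigenvalue is positive the solve fails with an explicit
  "no positive spectrum" error rather than returning an empty geometry.
* Eigenvector signs are canonicalized so each column's largest-magnitude
  entry is positive, making output reproducible across LAPACK builds. For
  degenerate (tied) eigenvalues any orthonormal basis of the eigenspace is
  acceptable; tests on tied spectra compare distance matrices, not raw
  coordinates.
* Subsets smaller than `m + 1` cannot support an `m`-dimensional block
  embedding and are rejected with advice to lower `m` or `p`.
* Target dimensionality defaults to `m = 2`, the visualization use case.

## Problem sizes

The test suite runs exact-recovery sweeps at `n ∈ {10, 60, 200}`,
brute-force equivalence at `n ≤ 8` (one-shot) and subsets of at most 12
(MaxMin), and the clustered accuracy benchmark at `n = 2000` with
`p = 10`, `s = 100` over 20 seeds per sampling strategy — the same sizes
the acceptance script uses. These sizes keep a full run in the minutes
range on one CPU while still exercising the divide-and-conquer machinery
at a genuinely partitioned scale.

## Known limitations

* The stitched solution is not iteratively refined; blocks are aligned to
  the anchor frame once.
* Anchors are disjoint across subsets by construction; shared-anchor or
  overlapping-block schemes are out of scope.
* Stress-based MDS (SMACOF), weighted MDS and missing dissimilarities are
  out of scope.
* `M_align` is embedded at the same `m` as the blocks; using a higher
  intermediate dimensionality for the anchor frame is unexplored here.
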