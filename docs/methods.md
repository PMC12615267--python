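# Methods

## The model

`hodgeflow` treats single-cell differentiation as a flow problem on a
2-dimensional simplicial complex (SC). Cells are 0-simplices; edges
(1-simplices) are potential differentiation events; triangles
(2-simplices) fill in locally dense regions so that only genuine
topological holes survive. The central objects are the oriented boundary
operators: `B1` (vertices × edges; −1 where an edge leaves a vertex, +1
where it enters) and `B2` (edges × triangles; +1 where the edge agrees
with the induced boundary orientation of the triangle, −1 where it
opposes it). Edges point from low to high vertex index and triangles are
ascending triples, so both operators are determined by bookkeeping;
`B1·B2 = 0` holds exactly in integer arithmetic.

The first-order Hodge Laplacian `L1 = B1ᵀB1 + B2B2ᵀ` acts on edge
signals. Its kernel — the harmonic space — has dimension equal to the
first Betti number (number of independent 1-cycles), and every harmonic
vector is orthogonal to both gradient flows (`im B1ᵀ`) and curl flows
(`im B2`). We use the degree-normalized form

    L1n = D2 B1ᵀ D1⁻¹ B1 + B2 D3 B2ᵀ D2⁻¹

with `D2 = max(diag(|B2|·1), I)` (triangle-adjusted edge degrees),
`D1 = diag(|B1| D2 1)` (D2-weighted vertex degrees; an optional scale
factor is exposed since published variants differ by a factor of 2, which
cannot change the kernel dimension) and `D3 = I/3`. The eigenproblem is
solved on the symmetric conjugate `L1s = D2^{-1/2} L1n D2^{1/2}` and
eigenvectors are mapped back as `U = D2^{1/2} Q`. Eigenvalues below
`1e-8 × λ_max` count as zero; a dense solver is used up to 2,000 edges
and a shift-invert Lanczos solver (shift −10⁻³, enlarged and retried if
every returned eigenvalue is null) beyond that. The two routes agree on
the harmonic count and, up to sign, on the harmonic line.

A differentiation tree has no holes by itself. They are manufactured:
after pseudotime estimation, every group of terminally differentiated
cells is connected back to the progenitor cells by *dummy* simplices, so
each fate contributes one independent cycle and the harmonic dimension
counts fates.

## Pipeline stages, parameters, defaults

**Diffusion graph.** Locally scaled Gaussian kernel
`W_ij = exp(−‖x_i−x_j‖²/σ_iσ_j)` with `σ_i` the distance to the
`scale_neighbor`-th nearest neighbour (default 7, the standard
local-scaling choice; duplicate points fall back to the smallest positive
neighbour distance). `W_ii = 1` (the formula value) and degrees include
it. The random-walk operator `M = D⁻¹W` is iterated `steps = 100` times
from the uniform root indicator; the spectral form through
`M' = D^{-1/2}WD^{-1/2}` is mathematically identical and kept for
moderate sizes, plain matrix-vector iteration is used at scale. Mass is
conserved exactly (`Σu = 1`).

**Pseudotime scale.** The diffusion mass decays like `exp(−d²/4s)` in
graph distance `d` (the Varadhan regime), so neither `u` nor `log u` is a
usable ordinate: min-max normalizing `−u` saturates (we measured 75 % of
cells above pseudotime 0.99998 on simulated trees) and `log u` is
quadratic in distance, compressing all shallow structure into a narrow
band near the root. The pipeline therefore refines the potential
`−√(log u_max − log u)`, which is approximately linear in graph distance;
pseudotime is its min-max-normalized negation (roots at 0, terminal
cells near 1). This is a monotone rescaling of the same diffusion
potential — orderings are unchanged.

**Gradient refinement.** Full-graph gradients `w_ij = u_j − u_i` are
transferred to the pruned union-kNN graph (`knn_k = 15`) by minimizing
`‖B1^F w^F − B1^P w_P‖² + λ‖w_P‖²`; the complete-graph divergence
`B1^F w^F = n·u − Σu` is evaluated in closed form. `λ` defaults to
`0.01 × λ_max(B1^Pᵀ B1^P)` (dimensionless ridge). A least-squares
re-integration `min_u ‖B1^Pᵀu − w_P‖²` gives the smoothed potential,
gauge-fixed to zero mean over the roots.

**Layout.** Pairwise targets are graph shortest-path distances with
embedding-metric edge lengths; SMACOF stress majorization (deterministic
classical-MDS initialization, ≤ 300 iterations, relative tolerance 1e−6)
gives the 2-D coordinates. Stress is non-increasing and the layout is
reproducible under a fixed seed. The layout only needs enough metric
fidelity for triangulation; it is not a visualization.

**Complex construction.** Delaunay triangulation of the layout, then
long-edge filtering: default removes edges above `3 × Q75` of the edge
length distribution (triangles losing a side are removed with them); the
alternative selects edges below `1.2 ×` the single-component radius (the
longest Euclidean-MST edge, i.e. the last 0-dimensional persistence
death).

**Terminal groups.** Peaks of pseudotime are extracted by 0-dimensional
persistence of the superlevel filtration on the pruned kNN graph (the 2-D
complex adjacency is unsuitable: a planar layout of a tree places
unrelated branches side by side). A peak whose persistence is below
`terminal_persistence = 0.025` (pseudotime units on the Varadhan scale)
is a noise wiggle and is absorbed; survivors become terminal groups with
their superlevel basins. Groups peaking below `0.02 × max pseudotime`
are discarded — on all simulations those are noise blobs on the far side
of the root (measured peak pseudotimes ≤ 0.01 versus ≥ 0.03 for the
shallowest genuine tips). The persistence default is an operating point
chosen from measured persistence distributions on simulated trees: true
tips concentrated at ≥ 0.05 and absorbed or spurious peaks at ≤ 0.026,
with a small overlap zone around 0.02–0.03 where resolution is genuinely
ambiguous (see Limitations).

**Dummy links.** Each terminal group is coned onto the complex: apex =
the lowest-pseudotime cell, base = the group's `m = 5` highest-pseudotime
cells restricted to one connected patch; dummy edges run base→apex and
dummy triangles fill the cone over every base-internal edge. A cone is
contractible and intersects the complex in exactly two pieces (base and
apex), so by Mayer–Vietoris each group closes exactly one hole: the final
Betti number — and hence the harmonic dimension — equals the number of
terminal groups in the root's component. (A local re-triangulation of
terminal and root cells, the more obvious "thick bundle" construction,
is not used: dropping its one-sided triangles punches uncontrolled extra
holes, which we observed directly as 7 harmonics on a 2-fate cloud.)

**Trajectory sampling.** Walks start uniformly at the `m` lowest-
pseudotime cells and step to a uniformly chosen neighbour of strictly
higher smoothed pseudotime, stopping at local maxima; `n_paths = 10,000`
by default. Uniform choice over ascending directions (rather than
magnitude-proportional) keeps weak-gradient side branches populated —
under magnitude weighting we measured a full-length branch receiving
0.1 % of walks versus 5.7 % uniform. Walks that terminate outside every
detected terminal-group basin died at a spurious maximum (typically the
root noise shell) and are discarded; groups must then absorb at least
`group_min_flux = 0.5 %` of the surviving walks (the same fraction as
the trajectory outlier rule), which prunes terminal candidates that no
sampled differentiation actually reaches.

**Flows, embedding, clustering.** Each walk is lifted onto the SC
(missing steps replaced by layout-weighted shortest paths; loops arising
from detours are erased so lifted paths are vertex-simple), encoded as a
signed `{−1,0,+1}` edge flow, and projected onto the harmonic basis.
DBSCAN groups the path embedding; `eps` defaults to the median 5-NN
distance, floored at 0.15 × the median centroid distance because
identical short paths create exact duplicates that collapse the naive
median. Clusters below 0.5 % of paths are outliers; clusters whose walks
end in the same terminal group are merged, keeping the larger.

**Tree inference.** Prefix sums of the signed step indicators give each
walk a curve in harmonic space (its endpoint reproduces the path's
embedding exactly — asserted ensemble-wide). Per group, every traversed
edge is placed at the mean curve point over its visits; edges are binned
by pseudotime (mean of endpoint pseudotimes) on a common grid of
`bins = 10` spanning the union of all groups' ranges. Anchoring the grid
to the shortest group's range — a defensible reading of the procedure —
collapses everything beyond that range into one bin on deep trees (we
measured a grid covering [0, 0.28] of a [0, 1] pseudotime), so the union
range is used. Per (group, bin): backbone = mean coordinate, compactness
= mean pairwise distance (ordered pairs, self included). Two groups
branch at the last bin where
`‖b̄_i/σ̄_i − b̄_j/σ̄_j‖ < σ` (default 1); pairs never that close share
only the root and branch at bin 0. Bottom-up merging (highest branching
bin first; ties broken by smallest group index) yields the milestone
tree; every cluster becomes a branch between the milestone that created
it and the one that consumed it.

**Cell allocation.** A cell takes the trajectory group whose walks visit
it most often; cells no walk visits are placed at the mean cumulative
coordinate of their visited non-dummy incident edges and fall to the
nearest group backbone at their pseudotime bin; remaining cells inherit
the branch of the nearest located cell in the layout. The branch is the
tree edge carrying the chosen group over the cell's bin; the
within-branch position is the cell's pseudotime rescaled to the branch
span (needed for milestone-percentage export; the choice is ours).

**Downsampling.** With `downsample_fraction` set, the fit runs on a
seeded uniform cell subsample (roots always kept) and the remaining
cells inherit the assignment of their nearest sampled neighbour in the
input embedding.

**Markers and regulators.** For a branch contrast, cells from the
terminal half of each branch's positions are compared gene-by-gene on
log1p library-normalized counts with a Welch t-test, cells weighted by
their trajectory visit counts. Weights are normalized per group to the
nominal sample size, so uniform visits reduce exactly to the unweighted
test and rescaling all visits is a no-op; a rank-sum alternative is
available. P-values are Benjamini–Hochberg corrected. Regulator ranking
correlates per-bin mean TF expression (smoothed by a reflect-padded
moving average, window 5, odd) with per-bin mean TF activity along the
branch and sorts by Pearson correlation; constant profiles are dropped
with a warning. TF activities (e.g. motif-accessibility scores) are an
input, never computed here.

## Synthetic data

The generator grows diffusion-limited-aggregation (DLA) trees: each of
`n_branch` branches is a cumulative standard-normal walk of
`branch_length` steps in `n_features` dimensions, started at a uniformly
chosen point of a uniformly chosen existing branch; i.i.d. Gaussian noise
of standard deviation `noise_sd` is added to every coordinate. Defaults
follow the simulation protocol the method is evaluated on: 3,000 points,
100 features, noise 5. A geometric multifurcation cloud (root segment
fanning into unit arms, used at 600 points with noise 0.05) provides
fully controlled 1/2/3-fate fixtures. Identical seeds give bit-identical
data.

Ground truth needs care: a branch whose last attachment lands near its
parent's tip absorbs that tip — the leftover stub is buried in the noise
ball and no method (nor a human) can call it a distinct fate. A tip
counts as a *realized leaf* when its backbone displacement from the last
attachment exceeds 1.5 × the pairwise-noise scale
`noise_sd·√(2·n_features)`; *realized branch labels* likewise merge
stretches with identical downstream realized-leaf sets (walk-level ids
are a misleading target: an exactly recovered realized tree still mixes
walk ids on contracted stretches, with a measured agreement ceiling near
0.62 on such seeds). The 1.5-σ constant is a resolution definition, not
a fit to the method; trees whose stubs sit at that boundary flip either
way.

What the generator does *not* emulate: count noise and library-size
variation, dropout, batch effects, density gradients along branches,
cycles, or converging fates. Passing tests on these data show the
geometric/topological machinery recovers branching structure at a
realistic noise level — not robustness to the full error structure of
real scRNA-seq.

## Problem sizes used in validation

Tree-recovery validation runs simulated trees (3,000 points, 100
features, noise 5; `n_branch ∈ {3, 5, 8}`; 10 seeds each) through a
20-component PCA (the pipeline always consumes a low-dimensional
embedding; the raw 100 noisy coordinates degrade the local-scaling
kernel), fitting on a seeded 50 % cell subsample with 3,000 sampled
walks. Fifty percent sits between the full-scale protocol and the 30 %
time-efficient variant; at 30 % the shortest resolvable stub roughly
doubles, which is what the subsample trades away. Measured under these
conditions: realized-leaf recovery 9/10, 10/10, 9/10 and median
realized-branch agreement 0.91.

## Numerical choices and degenerate inputs

Kernel symmetrized to machine precision; isolated vertices rejected with
the offending cell named. λ = 0 with a rank-deficient transfer system
returns the minimum-norm LSQR solution with a warning. Collinear layouts
fail Delaunay with guidance. Singleton bins substitute the global median
compactness. Branch-bin ties break deterministically. All randomness
flows from a single integer seed (sub-seeds are fixed offsets); two runs
with equal configuration are identical, including DBSCAN labels and the
newick string.

## Known limitations

- Fates closer than the noise resolution (~1.5 pairwise-noise sigmas
  here) cannot be separated, and near that boundary leaf counts can be
  off by one in either direction; the persistence threshold is an
  operating point inside a measured but slightly overlapping gap.
- One hole per terminal group requires the terminal group to lie in the
  root's connected component after edge filtering; otherwise the fate is
  reported but contributes no harmonic direction (a warning fires).
- The 2-D layout is only metrically faithful enough for triangulation;
  strongly intertwined high-dimensional branches may still cross in the
  plane, which inflates shortest-path detours during lifting.
- Pseudotime inherits diffusion assumptions: a single connected process,
  one root population, density not too far from uniform along branches.
- Converging or cyclic differentiation violates the tree model by
  construction.
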