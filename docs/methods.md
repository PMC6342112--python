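# Methods

This note documents the models, statistics and numerical choices behind the
package, and what its validation does and does not establish.

## From records to the bipartite incidence

Coordinates are taken as already projected, in meters; the package is
CRS-agnostic and any reprojection is a pre-step. The analysis grid uses
half-open square cells `[x0 + c·l, x0 + (c+1)·l) × [y0 + r·l, y0 + (r+1)·l)`
with the origin snapped down to a multiple of the cell size *l*, so every
record maps to exactly one cell, boundary records are deterministic, and
grids built from different subsets of the same survey align. Defaults follow
common practice for dense regional floristic surveys: *l* = 5,000 m and a
georeferencing-precision filter that keeps records strictly below 10 m.
Records with *missing* precision are kept by default (surveys often omit the
field for precise GPS records); a strict flag drops them. Sub-taxon
aggregation truncates labels at the parent binomial — at the first
infraspecific marker (`subsp.`, `var.`, …), else at two tokens — with an
optional explicit synonym map for irregular cases. No minimum-prevalence
filter is applied by default; both per-cell and per-species minima exist as
options. Presence is binary: abundance and record counts per cell are
deliberately ignored, matching the presence–absence framing of the
similarity index.

## Similarity projection

Cell–cell weights default to the Jaccard index; Simpson (shared richness
over the smaller set) is offered as a turnover-oriented alternative less
sensitive to richness gradients. Intersections are counted by one sparse
product of the incidence with its transpose, so the dense cell × cell matrix
is never materialized. All positive edges are kept by default; `min_weight`
is an inclusive lower bound except that exact-zero weights are always
dropped (a pair with no shared species has no edge — this also makes
`min_weight = 1` mean "identical composition only"). A per-node top-k
sparsifier (union of each node's strongest edges, ties at the cut going to
the lower opposite node id) exists for grids much larger than the defaults;
it is off by default because a few thousand cells are tractable dense.

## Significance-aware community detection

Bioregions must be more than the output of a partitioning heuristic: the
package follows the order-statistics local-optimization approach in which a
cluster counts only if it is unlikely under a null model that preserves each
node's connectivity profile.

**Per-node score.** For node *u* in candidate cluster *C* within a connected
component, the null keeps *u*'s degree d_u and its multiset of incident
weights, and re-draws the endpoints of its edges with probability
proportional to degree. The internal strength W is then a weighted sum of
Bernoulli indicators with hit probability p = d_{C∖u} / (D − d_u) (D = total
stubs in the component); its tail probability r_u = P(W ≥ w_in) is evaluated
by a normal approximation with a continuity correction of half a typical
incident weight (keeping the tail valid where W is near-discrete). A
Monte-Carlo version of the same score (`cluster_significance`) draws the
endpoint indicators explicitly, with the usual (1 + exceedances)/(n_null + 1)
estimate; it serves as the user-facing scorer for arbitrary clusters and as
a cross-check of the analytic approximation.

**Order-statistics combination.** The members' r-values are sorted and the
k-th smallest is compared with the Beta(k, N − k + 1) law of the k-th order
statistic of N uniforms, N being the component size — as if the cluster had
been assembled from the component's most internally connected nodes. Only
ranks with r ≤ 1/2 count as evidence, and the best rank is Šidák-corrected
over the cluster size. A singleton or a whole component carries no partition
evidence and scores 1.

**Selection-aware calibration.** Modularity optimization searches over
subsets, so even corrected per-node scores are optimistically biased on null
networks. The detector therefore converts a candidate's combined score into
the probability of *finding* such a cluster: the identical procedure
(proposal runs, trimming, scoring) is executed on `n_null_networks`
(default 19) randomizations of the component — double-edge-swap rewiring
plus a weight shuffle for sparse graphs, the weight shuffle alone for dense
ones, where swaps barely change anything — and the candidate's empirical
p-value is its score's rank among the null minima. Acceptance requires this
probability to be below the tolerance (default 0.1; `n_null_networks` must
satisfy 1/(B+1) < tolerance). Reported cluster significances are therefore
floored at 1/(B+1). This makes the false-discovery behavior calibrated by
construction, which the test suite verifies empirically on randomized
networks.

**Proposals, trimming, refinement.** Candidates come from Leiden weighted
modularity optimization (best of `n_runs` seeded restarts, chosen by summed
cluster evidence). Each candidate may shed up to 10% of its weakest members
when that lowers its score; the Šidák step always uses the original size so
trimming cannot manufacture evidence. Accepted clusters are then re-analyzed
on their induced subgraphs (up to two levels), undoing the resolution limit
of modularity — small but significant communities inside a larger accepted
one are separated. A refinement is kept only if it genuinely detaches the
parts: the sub-clusters' mutual per-pair similarity must not exceed twice
the parent's background similarity to the rest of the graph. Without this
guard, any smooth similarity gradient (e.g. a continuum of test-value
profiles) would be sliced into arbitrary bands, since adjacent bands of a
gradient remain far more attached to each other than to the background; the
known cost is that genuinely nested hierarchies whose sub-communities stay
mutually attached are reported at the coarser level (with the finer look-up
left to the hierarchy diagnostic).

**Post-processing.** Nodes of rejected candidates are re-attached to the
cluster maximizing their summed edge weight (ties to the lowest cluster id,
iterated to stability); nodes with no edge to any cluster become flagged
singletons. Disconnected components are analyzed separately, so two isolated
cliques are two clusters without any significance hurdle. A quotient-graph
pass over the final clusters looks for a coarser significant level and
stores it as hierarchy level 1 with per-supercluster scores in diagnostics.

**Cross-check detectors.** `modularity` returns the plain Leiden partition
(raw combined scores still reported, uncalibrated); `ward` cuts a Ward
dendrogram of the 1 − weight dissimilarity at a user-chosen K and is the
deterministic, non-network baseline. Both exist to show that well-separated
structure does not depend on the primary detector.

## Test values

The statistic compares the observed number of cells n_ij supporting species
*i* in region *j* with the n_i n_j / n expected under uniform placement of
the species' cells, normalized by the exact hypergeometric standard
deviation σ_ij = sqrt(n_i n_j (n − n_i)(n − n_j) / (n²(n − 1))) — symmetric
in the species/region roles. Degenerate cases with σ_ij = 0 (species
everywhere, or a single region) are defined as ρ = 0: such a species is
present in exact proportion wherever it is. The closed form is validated two
ways: against scipy's hypergeometric moments, and against an independent
simulation oracle (`empirical_moments`) that places n_i cells uniformly at
random 10⁴ times and measures the moments directly.

The contribution spectrum tabulates, over a δ grid (default −1 to 6), the
fraction of species contributing (ρ > δ) to exactly k regions. It is
monotone by construction: raising δ can only move species toward k = 0.

## Species groups and the coarse-grained network

The similarity kernel s = 1/(1 + d²), with d² the squared Euclidean distance
between two species' ρ profiles, is used as typeset in the source
literature; a 1/(1 + d) variant sits behind a flag since both are monotone
transforms of d and group structure is expected to be robust to the choice.
Group profiles report the five-number summary of ρ per (group, bioregion)
with type-7 (linear-interpolation) quartiles, flagging medians above δ.

Coarse graining keeps strictly-above-δ contributions (a value exactly at the
threshold is not significant), normalizes each contributing species' values
to sum to one *across bioregions* — the only reading under which the rows of
λ sum to one — and averages them over each region's contributor set.
Regions with an empty contributor set yield flagged NaN rows rather than
being dropped; if every set is empty the threshold was too strict and an
error asks for a lower δ. λ is never symmetrized: the asymmetry between
λ_jj′ and λ_j′j is a detectable signal of hierarchical relationships. The
display threshold (default 10%) applies only to the exported coarse graph;
the full matrix is always written. A `merge_regions` helper sums ρ⁺ columns
and unions contributor sets, supporting the sanity property that merging two
regions never drops the merged diagonal below the smaller of the two
originals.

## Synthetic data

The generator emulates a dense regional occurrence survey: a rectangular
grid, planted bioregions as the nearest-seed (discrete Voronoi) tessellation
of uniformly drawn seed cells — convex-ish, rook-contiguous patches, ties to
the lowest region id — and two species classes. Faithful species get a home
region (balanced round-robin) and appear in each cell independently with
probability p_in at home and p_out away; widespread species use p_wide
everywhere. One record per presence is emitted at the cell center with 1 m
precision, in the exact input dialect of the gridding module. All
randomness derives from a single integer seed through spawned generator
streams (geometry, species assignment, sampling), so each part is
independently reproducible.

The reference validation scenario uses a 20 × 20 grid, 4 regions, 800
species, p_in = 0.5, p_out = 0.03, 10% widespread at p_wide = 0.5, seed 101
— roughly 150 species per cell, most species on under ~15% of the grid, and
a long tail of widespread ranges, the qualitative degree-distribution shape
of dense floristic surveys. Independent Bernoulli presences mean the
generator has *no* within-region spatial autocorrelation, no abundance
structure, no detection bias and no richness gradients; passing the recovery
tests therefore shows the pipeline is correct and calibrated under its own
assumptions, not that real surveys are this easy. Validation problem sizes
(400 cells × 800 species for recovery; 60-node networks, 20 replicates for
calibration; 10⁴ placements for the moment oracle; detector restarts set to
5 in the harness) were chosen so the full suite completes in a few minutes
while leaving the statistical checks well-powered.

Expected-value helpers (per-cell richness, per-species range size) provide
the binomial oracles the tests compare against, within three standard
errors. With regions covering ≈25% of the grid and p_in = 0.5, a faithful
species occupies ≈15% of cells — restricted ranges dominate (<10% of cells)
only once home regions shrink to ≈12% of the grid, which is where that
property is checked.

## Degenerate inputs and numeric details

Empty species sets are errors for pairwise similarity; empty networks and
empty clusters are parameter errors. r-values are clipped to [1e−300, 1] and
all order-statistic algebra runs through `log1p`/`expm1` to survive extreme
tails. Cluster ids are assigned deterministically (components in index
order; within a component by descending size, then smallest member index),
so identical inputs and seeds give byte-identical outputs; partitions are
permutation-equivariant up to this relabeling. The pipeline manifest
records config, input SHA-256, derived stage seeds, library versions and
per-stage counts/timings; deterministic stages re-run bit-identically from
it.

## Known limitations

- The significance calibration answers "could this cluster arise in a
  degree/strength-preserving random network"; it does not model spatial
  autocorrelation, so on strongly autocorrelated but regionless data it can
  report spatially coherent noise as significant. A spatially explicit null
  is out of scope.
- The refinement guard trades nested-hierarchy resolution for robustness to
  similarity gradients (see above).
- Reported cluster significances are floored at 1/(n_null_networks + 1);
  resolving much smaller tolerances requires proportionally more null
  networks.
- Sub-taxon aggregation is purely lexical; taxonomic synonymy beyond the
  optional user-supplied map is out of scope.
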