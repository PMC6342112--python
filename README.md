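# bioregions

Network-based delineation of biogeographical regions from georeferenced
species occurrence records.

Biogeographers delimit *bioregions* — spatially coherent territories with
internally similar species composition — to understand the ecological and
historical drivers of species distributions and to support conservation
planning. This package implements a five-step network workflow for doing so
from a raw occurrence table:

1. **Bipartite network.** Records are cleaned (georeferencing precision
   strictly below a threshold, optional taxon exclusions, sub-taxa aggregated
   to species), snapped to a square grid of lateral size *l* (default 5 km),
   and collapsed into a binary cell × species presence structure.
2. **Spatial projection & bioregions.** Grid cells are linked by the Jaccard
   index of their species sets, J(A, B) = |A∩B| / |A∪B| ∈ [0, 1], and
   statistically significant communities of this weighted network become
   bioregions. The detector proposes communities by weighted modularity
   optimization and accepts one only when the probability of finding an
   equally extreme cluster in a degree/strength-preserving random null model
   is below a tolerance (default 0.1). Spatial coherence is reported as the
   largest rook-contiguous patch fraction.
3. **Test values.** Each species *i* is scored against each bioregion *j*
   with the test value (valeur-test)

       ρ_ij = (n_ij − n_i n_j / n) / σ_ij,
       σ_ij² = n_i n_j (n − n_i)(n − n_j) / (n² (n − 1)),

   the z-like deviation of the observed in-region cell count n_ij from its
   expectation under uniform placement, with the hypergeometric standard
   deviation. A species *contributes* to a bioregion when ρ_ij > δ
   (default δ = 1.96, the 2.5% Gaussian upper tail).
4. **Species groups.** Species are linked by
   s_ii′ = 1 / (1 + Σ_j (ρ_ij − ρ_i′j)²) and grouped with the same
   significance-aware detector, yielding sets of species with shared spatial
   behavior.
5. **Coarse-grained network.** Keeping only significant contributions
   (ρ⁺ = ρ·1{ρ > δ}), normalizing them per species (ρ̂⁺), and averaging over
   each region's contributor set A_j = {i : ρ_ij > δ} gives the interaction
   matrix λ_jj′ = (1/|A_j|) Σ_{i∈A_j} ρ̂⁺_ij′. Each row sums to one; the
   diagonal λ_jj is the region's *specificity* and the (generally
   asymmetric) off-diagonal entries quantify directed relationships between
   regions.

A synthetic-data module generates occurrence tables with planted contiguous
bioregions and species of known home region, so the whole pipeline is
testable end to end without any external database.

## Worked example

Simulate a 10 × 10 km grid with three planted bioregions and 150 species,
then run the full pipeline:

```sh
bioregions simulate --out sim --seed 13 --n-rows 10 --n-cols 10 \
    --n-regions 3 --n-species 150 --p-in 0.6 --p-out 0.02
bioregions run-all --input sim/occurrences.csv --out run --seed 3
```

or in Python:

```python
import bioregions as br

scen = br.make_scenario(n_rows=10, n_cols=10, n_regions=3, n_species=150,
                        p_in=0.6, p_out=0.02, seed=13)
occ_path, truth = br.write_scenario(scen, "sim")
manifest = br.run_pipeline(occ_path, "run", config=br.PipelineConfig(seed=3, n_runs=3))
```

The run directory then contains, among other outputs, `cluster_report.csv`:

```
 cluster  size  significance  connectivity
       1    52          0.05           1.0
       2    38          0.05           1.0
       3    10          0.05           1.0
```

Three bioregions were detected from 3,646 records (100 occupied cells ×
150 species, 4,939 cell-cell edges); each is significant at the 0.1
tolerance (significance is the estimated probability of finding such a
cluster in the degree-preserving null model, floored by the number of null
networks) and perfectly contiguous (connectivity 1.0). `lambda_pct.csv`
holds the interaction matrix in percent:

```
               1      2      3
bioregion
1          100.0    0.0    0.0
2            0.0  100.0    0.0
3            0.0    0.0  100.0
```

At this strong planted separation every region is perfectly specific
(λ_jj = 100%): species contributing significantly to a region contribute
only to it. `spectrum.csv` tabulates the contribution spectrum — at
δ ≈ 1.9, 91% of species contribute to exactly one region and 9% to none
(the widespread species, which track no region). The partition matches the
planted one (`br.evaluate_recovery` reports an adjusted Rand index of 1.0),
and `species_groups.csv` recovers four groups: one per planted region plus
one of widespread species.

Every output is plain text (CSV/TSV, matrix market, GeoJSON, GraphML), and
`manifest.json` records the config, input digest, derived seeds, versions
and per-stage counts and timings needed to reproduce the run.

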