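# Methods

## Problem and model

The package compares immune gene co-expression networks between tissue
conditions. A network for one condition is an undirected simple graph whose
nodes are immune genes and whose edges are gene pairs with a strong,
statistically significant positive Pearson correlation across that
condition's samples. Networks are then summarized by a fixed 13-parameter
topological profile and compared as points in that 13-dimensional space.

### Correlation and edge definition

For genes *x*, *y* over *n* samples, *r* is the ordinary Pearson
correlation; its two-sided p-value comes from the exact small-sample test
*t* = *r*·√((*n*−2)/(1−*r*²)) with *n*−2 degrees of freedom (|r| = 1 maps
to p = 0; *n* < 3 is an error). An edge requires **r ≥ r_min AND
p < p_max**, default r_min = 0.95, p_max = 0.05.

Deliberate conventions:

- **Sign-sensitive threshold.** The default keeps only strong *positive*
  co-expression (r ≥ 0.95), not |r| ≥ 0.95; `absolute_r=True` switches to
  the two-sided variant. At this threshold the difference is small but not
  zero.
- **No multiple-testing correction** on the ~N²/2 pair tests; the choice is
  logged loudly. At r ≥ 0.95 the p-threshold is essentially never the
  binding constraint for realistic n, so correction would not change the
  networks; it is omitted to match the convention of the analysis this
  package reproduces.
- **Zero-variance genes** are dropped (with a warning) immediately before
  correlation — Pearson r is undefined for them — keeping the expression
  module purely transform-oriented.
- **Isolated genes are not nodes.** The graph contains only genes incident
  to at least one edge; the connected-gene and universe counts are logged.
- r is compared with the threshold exactly as a floating value; no
  rounding.

### Input scale

Which value scale feeds the correlation is a genuine open choice; the
package defaults to log2(CPM+1) as the standard variance-stabilizing
transform for RNA-seq counts, and supports `cpm` and `none` (the synthetic
Gaussian benchmark uses `none`, since its values are already latent-normal).
No claim is made that any particular published analysis used one of these
specific transforms.

### Group-size matching

When two conditions have unequal sample counts the larger is down-sampled
without replacement with a seeded generator (`numpy.random.default_rng`),
so both correlation estimates carry equal n. The selection is reproducible
given the seed and preserves column order.

## The 13-parameter profile

Order is a fixed contract (vector positions and JSON key order):
nodes, edges, average_neighbors, diameter, radius, path_length,
clustering_coefficient, density, heterogeneity, centralization,
connected_components, assortativity, modularity.

- **average_neighbors** is the mean count of distinct neighbors, equal to
  2L/N on simple graphs (asserted as a property test).
- **Shortest-path statistics are computed over finite pairs only.**
  Thresholded co-expression networks are routinely disconnected (tens of
  components), so diameter = max finite BFS distance, radius = min over
  nodes of within-component eccentricity, path length = mean finite
  pairwise distance. This matches the NetworkAnalyzer-style treatment and
  avoids restricting to the largest component.
- **Clustering** C_i = 2L_i/(k_i(k_i−1)) with C_i = 0 for degree < 2, and
  ⟨C⟩ averages over *all* nodes including those zeros.
- **Heterogeneity** defaults to var(k)/mean(k) with *population* variance
  (the degree sequence is a complete enumeration, not a sample);
  `convention="cytoscape"` gives √var/mean, the coefficient of variation
  Cytoscape's NetworkAnalyzer prints. Both conventions are 0 on regular
  graphs.
- **Centralization** is Freeman degree centralization
  (N/(N−2))·(k_max−⟨k⟩)/(N−1): 1 for a star, 0 for regular graphs. (A
  per-node degree centrality cannot itself yield a single network value;
  this is the standard network-level summary of it.)
- **Assortativity** is the Pearson correlation of degrees over edge
  endpoints with both orientations of every edge included. It is undefined
  (NaN, warned) when endpoint degrees have zero variance — stars, cycles,
  any regular graph.
- **Modularity** Q = (1/2L)Σ_ij (A_ij − k_i k_j/2L) δ(c_i, c_j), evaluated
  for the partition returned by greedy (Clauset–Newman–Moore)
  agglomeration. The algorithm is deterministic for a fixed node insertion
  order; a `seed` parameter is part of the call contract so pipelines can
  thread one seed everywhere. Communities are returned sorted by smallest
  member for stable output.

### NaN policy in comparisons

A NaN profile entry (undefined assortativity) is kept in the vector. When
two vectors are compared, positions NaN in *both* are skipped with a
warning; a NaN on one side only raises, so a dimension never silently
drops.

## Distances

euclidean = √Σ(a−b)², manhattan = Σ|a−b|, cosine = 1 − a·b/(|a||b|) (the
*distance*, not the similarity — the published values this package
reproduces are only consistent with the distance form). Components are
**not** standardized by default: the reproduced analysis used raw profile
vectors, where node and edge counts dominate. `zscore=True` standardizes
each component across the profiles being compared (population SD; constant
components are zeroed) for a methodologically cleaner comparison.

The bundled reference file (`immunetwork/data/gse120622_profiles.json`)
transcribes the published 13-parameter profiles of the GSE120622 normal /
LUAD / LUSC networks. Computing distances on those vectors reproduces the
published figures at the precision they were printed — note the publication
truncates rather than rounds its last digit (e.g. the exact Manhattan
normal→LUAD value on the printed vectors is 1831.873, printed 1831.8;
cosine normal→LUSC is 0.05139, printed 0.0513). No attempt is made to
recompute the profiles themselves from the raw GEO data: that would require
unstated preprocessing choices, and the published table's internal ratios
(e.g. average neighbors vs 2L/N) are not fully self-consistent.

## Synthetic data

The generator emulates the *shape* of the study inputs: two conditions,
~1000 genes, ~20 samples per condition, with planted gene modules whose
within-module correlation differs between conditions plus independent noise
genes.

- **Latent model**: zero-mean multivariate normal with block-exchangeable
  covariance — within module *m* in condition *c* every gene pair has
  correlation ρ_{m,c}, between modules zero. The exchangeable block is
  sampled exactly via its single-factor representation
  x = √ρ·f + √(1−ρ)·e, which is O(size·n) and valid for ρ ∈ [0, 1)
  (positive definiteness requires only ρ > −1/(size−1); the config
  restricts to non-negative ρ).
- **Count option**: `negative_binomial` maps the latent values through an
  exponential link onto log-normal per-gene baseline means (meanlog 5,
  sdlog 1.5, mimicking RNA-seq count scale) with gamma-Poisson
  overdispersion (dispersion 10). Gaussian is the default because it gives
  exact control of the latent correlations.
- **Determinism**: all randomness flows from the single config seed through
  one `default_rng`; identical configs give bit-identical matrices.
- **Canned benchmark** (`two_condition_scenario`): 1000 genes, 20% noise,
  20 samples per condition; six modules (sizes 134/134/133/133/133/133),
  all at ρ = 0.97 in "normal", three degraded to ρ = 0.5 in "tumor"; the
  ten functional categories assigned round-robin. This emulates the
  qualitative study finding of larger, more connected immune networks in
  normal tissue than in tumor.

### What recovery on the benchmark does and does not show

At ρ = 0.97 and n = 20 the sampling distribution of the empirical
correlation gives, per pair,
P(r̂ ≥ 0.95) ≈ Φ((atanh 0.97 − atanh 0.95)·√(n−3)) ≈ 0.86, and the shared
module factor makes per-module recall fluctuate strongly around that mean
(roughly 0.73–0.99 across seeds). Expected behavior at default thresholds
is therefore: **precision ≈ 1** (a null pair clears r ≥ 0.95 at n = 20
with probability ~1e−6, so false edges are rare even among ~450k null
pairs), **recall ≈ 0.8–0.9**, normal networks with about twice the edges
and twice the connected genes of tumor networks, but normal/tumor *mean
degree* a near coin-flip (both conditions' connected genes come from
ρ = 0.97 modules, so ⟨k⟩ compares two equal-mean recall estimates). The
acceptance-level check that asserts recall ≥ 0.9 per seed and a consistent
mean-degree ordering is accordingly expected to fail for some seeds under
these study conditions; the failure reflects the sampling variance of the
scenario, not a defect of the reconstruction, and the scenario parameters
are fixed as stated rather than tuned.

The simulation does not attempt real-data features: no library-size
variation, batch structure, mean–variance coupling on the Gaussian path,
negative or between-module correlation, or cell-sorting composition
effects. Passing recovery tests therefore demonstrates correctness of the
pipeline mechanics and thresholds, not performance on real RNA-seq.

## Problem sizes and numerical choices

The test suite runs the full benchmark (1000 genes × 20 samples × 2
conditions × 5 seeds, ~500k correlations per network) in a few seconds;
exhaustive brute-force oracle comparisons use 50 random graphs of ≤ 8
nodes at 1e-10 tolerance. Hub ties break lexicographically by gene ID
(logged). Degenerate inputs: empty networks yield 0-with-warning for
average clustering/density/mean degree and errors for path statistics,
hubs, communities and heterogeneity; duplicate gene rows collapse by sum
(count semantics); duplicate sample IDs are a hard error; file round-trips
use round-trip float parsing so write→load is bit-identical.

## Known limitations

- The published per-network parameter values (node counts, hub genes,
  category percentages) are not reproduced from raw data — see above.
- Greedy modularity maximization is a heuristic; Q is reported for its
  partition, not the global optimum.
- The cosine distance on raw profiles is dominated by large-magnitude
  components, like the other metrics; the z-score option changes the
  numbers and is off by default for fidelity to the reproduced analysis.
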