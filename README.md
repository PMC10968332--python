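# immunetwork

Immune gene co-expression network topology and between-condition comparison.

## What this is for

Lung adenocarcinoma (LUAD) and lung squamous cell carcinoma (LUSC) respond
differently to immune checkpoint inhibitors, and one way to look for a
systems-level correlate is to ask how the *co-expression structure* of immune
genes differs between tumor and normal lung tissue. `immunetwork` implements
that analysis as a tested pipeline for anyone with a genes × samples
expression matrix and an immune-gene list:

1. **Network construction** — within each tissue group, compute Pearson's
   correlation *r* for every pair of immune genes and link the pairs with
   *r* ≥ 0.95 and *p* < 0.05 (two-sided t-test,
   *t* = *r*·√((*n*−2)/(1−*r*²)) on *n*−2 degrees of freedom). Genes are
   nodes, significant correlations are undirected unweighted edges, and
   genes without any qualifying partner are excluded. When one group has
   more samples than the other, the larger group is down-sampled at random
   (seeded, without replacement) so both networks rest on equal *n*.
2. **Topological profiling** — summarize each network by a fixed, ordered
   13-parameter profile: nodes *N*, edges *L*, mean degree ⟨k⟩, diameter,
   radius, characteristic path length, average clustering coefficient
   ⟨C⟩ = (1/N)ΣC_i with C_i = 2L_i/(k_i(k_i−1)), density d = L/(N(N−1)/2),
   degree heterogeneity var(k)/mean(k), Freeman degree centralization,
   connected components, degree assortativity (Pearson correlation of
   degrees across edge endpoints), and Newman modularity Q of a greedily
   detected community partition. Hub genes (maximum degree) and the
   functional-category composition of the network are reported alongside.
3. **Network comparison** — treat each profile as a 13-vector and measure
   how far each tumor network sits from the normal network under Euclidean,
   Manhattan and cosine (1 − similarity) distance. Components are not
   rescaled by default, matching the published analysis this package
   reproduces; a z-score option exists for scale-free comparisons.

A synthetic-data module generates two-condition expression matrices with
planted correlation modules (block-exchangeable multivariate normal latent
structure, optional negative-binomial counts), so the entire pipeline is
testable end to end — including precision/recall of edge recovery against
the planted truth — without downloading any real dataset.

## Worked example

The package ships the published topological profiles of the immune
co-expression networks built from GEO series GSE120622 (normal lung, LUAD,
LUSC). Comparing both tumor profiles with normal:

```python
import immunetwork as iw

profiles = iw.load_reference_profiles()
report = iw.compare_report(profiles, reference="normal")
print(report.to_string(index=False))
```

```
profile    metric    distance
   LUAD    cosine    0.002400
   LUSC    cosine    0.051391
   LUAD euclidean 1642.628940
   LUSC euclidean 2396.067219
   LUAD manhattan 1831.873000
   LUSC manhattan 2656.870000
```

Under every metric the LUAD network is closer to the normal-lung network
than the LUSC network is: the squamous tumors deviate more from normal
co-expression topology. (On the raw profiles these distances are dominated
by the node and edge counts; pass `zscore=True` to weigh all 13 parameters
equally.)

Running the pipeline on simulated data with six planted modules of strongly
co-regulated genes (the canned "normal" condition of the benchmark
scenario):

```python
matrices, truth, annotation = iw.two_condition_scenario(seed=1)
table = iw.pairwise_correlation(matrices["normal"])
net = iw.build_network(table, ann=annotation)   # r >= 0.95 and p < 0.05
print(net.number_of_nodes(), net.number_of_edges())   # 794 41553
print(iw.hub(net))                                    # ('G0161', 133)
print(iw.recovery_metrics(net, truth, "normal"))      # (1.0, 0.785...)
```

Every edge the network proposes is a planted within-module pair (precision
1.0); about 79% of planted pairs are recovered at this sample size (n = 20),
because an empirical correlation of a gene pair with latent ρ = 0.97
clears the 0.95 threshold only ~86% of the time on average (see
`docs/methods.md`).

## Layout

- `immunetwork.expression` — matrix I/O, CPM / log2(CPM+1) normalization,
  immune-gene selection, seeded group-size matching.
- `immunetwork.network` — pairwise correlation, t-distribution p-values,
  dual-threshold graph construction, TSV/SIF/GraphML export.
- `immunetwork.topology` — the 13-parameter profile and per-node reports.
- `immunetwork.distance` — profile vectors, the three distances, comparison
  reports, the bundled GSE120622 reference profiles.
- `immunetwork.simulate` — planted-module simulation, recovery scoring, the
  canned two-condition benchmark.
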