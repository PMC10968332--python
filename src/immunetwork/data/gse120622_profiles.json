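{
  "description": "Published topological parameters of the immune gene co-expression networks built from GEO series GSE120622 (normal lung tissue, lung adenocarcinoma, lung squamous cell carcinoma), transcribed in canonical 13-field order.",
  "source": "GEO accession GSE120622",
  "labels": [
    "nodes",
    "edges",
    "average_neighbors",
    "diameter",
    "radius",
    "path_length",
    "clustering_coefficient",
    "density",
    "heterogeneity",
    "centralization",
    "connected_components",
    "assortativity",
    "modularity"
  ],
  "profiles": {
    "normal": [385, 2704, 19.81, 22, 11, 6.463, 0.544, 0.078, 1.097, 0.216, 32, 0.605, 0.333],
    "LUAD": [228, 1069, 11.544, 10, 5, 3.765, 0.545, 0.064, 0.766, 0.121, 22, 0.375, 0.571],
    "LUSC": [156, 319, 10, 5, 3, 2.2, 0.762, 0.325, 0.507, 0.273, 30, 0.858, 0.765]
  }
}
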