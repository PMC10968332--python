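"""Synthetic two-condition expression data with planted correlation modules.

Generates genes × samples matrices whose genes fall into modules with a
configurable within-module correlation per condition (block-exchangeable
covariance, zero correlation between modules) plus uncorrelated noise genes.
The exchangeable block is sampled exactly through its single-factor
representation x = sqrt(rho)*f + sqrt(1-rho)*e, so the latent values are a
draw from the stated multivariate normal at O(module_size * n_samples) cost.
A negative-binomial option maps the latent values through an exponential
link onto log-normal per-gene means to mimic RNA-seq count scale.

The planted truth (module membership and which gene pairs carry latent
correlation above a threshold) supports precision/recall scoring of a
reconstructed network, and :func:`two_condition_scenario` provides the
canned benchmark emulating the study design: a "normal" condition with six
strongly correlated modules and a "tumor" condition in which half the
modules have lost most of their co-regulation.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CATEGORIES, ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module expression simulation.

    ``rho_by_condition`` maps each condition name to one within-module
    correlation per module (values in [0, 1)). Genes not assigned to a
    module are independent noise; their number is ``n_genes`` minus the sum
    of ``module_sizes``.
    """

    n_genes: int
    module_sizes: tuple[int, ...]
    rho_by_condition: Mapping[str, tuple[float, ...]]
    n_samples_per_condition: int
    count_model: str = "gaussian"
    nb_dispersion: float = 10.0
    nb_meanlog: float = 5.0
    nb_sdlog: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_condition <= 0:
            raise ValueError("n_genes and n_samples_per_condition must be > 0")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("modules must have at least 2 genes")
        if self.count_model not in ("gaussian", "negative_binomial"):
            raise ValueError("count_model must be gaussian or negative_binomial")
        for condition, rhos in self.rho_by_condition.items():
            if len(rhos) != self.n_modules:
                raise ValueError(
                    f"condition {condition!r}: need one rho per module")
            for size, rho in zip(self.module_sizes, rhos):
                # exchangeable block is positive definite iff rho > -1/(size-1)
                if not 0 <= rho < 1:
                    raise ValueError(
                        f"rho must be in [0, 1), got {rho} "
                        f"(positive-definite bound is rho > {-1/(size-1):.3g})")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_noise_genes(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    @property
    def noise_gene_fraction(self) -> float:
        return self.n_noise_genes / self.n_genes

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.rho_by_condition)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulation: module membership and latent rho."""

    module_of: Mapping[str, str | None]
    rho_by_condition: Mapping[str, Mapping[str, float]]  # condition -> module -> rho

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, module in self.module_of.items():
            if module is not None:
                out.setdefault(module, []).append(gene)
        return out

    def planted_pairs(self, condition: str, r_min: float = 0.95) -> set[Pair]:
        """Within-module pairs whose latent correlation is >= ``r_min``."""
        rhos = self.rho_by_condition[condition]
        pairs: set[Pair] = set()
        for module, genes in self.modules.items():
            if rhos[module] >= r_min:
                for a, b in itertools.combinations(sorted(genes), 2):
                    pairs.add((a, b))
        return pairs

    def to_tsv(self, path: str | Path) -> None:
        """Two-column ``gene_id<TAB>module`` table ('noise' for no module)."""
        with open(path, "w") as handle:
            for gene, module in self.module_of.items():
                handle.write(f"{gene}\t{module or 'noise'}\n")


def _gene_ids(config: SimulationConfig) -> tuple[list[str], dict[str, str | None]]:
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    module_of: dict[str, str | None] = {}
    cursor = 0
    for m, size in enumerate(config.module_sizes, start=1):
        for gene in genes[cursor:cursor + size]:
            module_of[gene] = f"M{m}"
        cursor += size
    for gene in genes[cursor:]:
        module_of[gene] = None
    return genes, module_of


def generate(config: SimulationConfig,
             ) -> tuple[dict[str, ExpressionMatrix], PlantedTruth]:
    """Simulate one expression matrix per condition plus the planted truth.

    All randomness flows from ``config.seed`` through a single generator, so
    a config generates bit-identical output on every call.
    """
    rng = np.random.default_rng(config.seed)
    genes, module_of = _gene_ids(config)
    n = config.n_samples_per_condition
    matrices: dict[str, ExpressionMatrix] = {}
    for condition in config.conditions:
        rhos = config.rho_by_condition[condition]
        latent = np.empty((config.n_genes, n))
        cursor = 0
        for size, rho in zip(config.module_sizes, rhos):
            shared = rng.standard_normal(n)
            noise = rng.standard_normal((size, n))
            latent[cursor:cursor + size] = (
                math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise)
            cursor += size
        latent[cursor:] = rng.standard_normal((config.n_noise_genes, n))
        if config.count_model == "gaussian":
            values = latent
        else:
            base_mean = rng.lognormal(config.nb_meanlog, config.nb_sdlog,
                                      size=config.n_genes)
            mean = base_mean[:, None] * np.exp(latent)
            size_param = config.nb_dispersion
            values = rng.negative_binomial(
                size_param, size_param / (size_param + mean)).astype(float)
        sample_ids = [f"{condition}_s{j + 1:02d}" for j in range(n)]
        frame = pd.DataFrame(values, index=genes, columns=sample_ids)
        group = condition if condition in ("normal", "LUAD", "LUSC") else "other"
        matrices[condition] = ExpressionMatrix(
            frame, {s: group for s in sample_ids})
    rho_map = {
        condition: {f"M{m + 1}": rho for m, rho in enumerate(rhos)}
        for condition, rhos in config.rho_by_condition.items()
    }
    return matrices, PlantedTruth(module_of, rho_map)


def recovery_metrics(net: nx.Graph, truth: PlantedTruth, condition: str,
                     r_min: float = 0.95) -> tuple[float, float]:
    """Precision and recall of network edges against planted module pairs.

    The positive set is the within-module pairs whose latent correlation in
    ``condition`` is at least ``r_min``. Precision is NaN for an edgeless
    network (no predictions); recall is then 0.
    """
    known = set(truth.module_of)
    unknown = set(net.nodes) - known
    if unknown:
        raise KeyError(f"network contains unknown gene(s): {sorted(unknown)[:5]}")
    positives = truth.planted_pairs(condition, r_min)
    edges = {tuple(sorted((u, v))) for u, v in net.edges()}
    if not edges:
        return math.nan, 0.0
    tp = len(edges & positives)
    precision = tp / len(edges)
    recall = tp / len(positives) if positives else math.nan
    return precision, recall


#: Canned two-condition benchmark: six modules of strongly co-regulated
#: genes in "normal"; in "tumor" three of the six retain rho = 0.97 while
#: three degrade to rho = 0.5, emulating loss of immune co-regulation.
SCENARIO_MODULE_SIZES = (134, 134, 133, 133, 133, 133)
SCENARIO_RHO = {
    "normal": (0.97, 0.97, 0.97, 0.97, 0.97, 0.97),
    "tumor": (0.97, 0.97, 0.97, 0.5, 0.5, 0.5),
}


def scenario_config(seed: int) -> SimulationConfig:
    """The canned scenario: 1000 genes (20% noise), 20 samples per group."""
    return SimulationConfig(
        n_genes=1000,
        module_sizes=SCENARIO_MODULE_SIZES,
        rho_by_condition=SCENARIO_RHO,
        n_samples_per_condition=20,
        count_model="gaussian",
        seed=seed,
    )


def two_condition_scenario(
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, ExpressionMatrix], PlantedTruth, GeneAnnotation]:
    """Generate the canned benchmark bundle (matrices, truth, annotation).

    The annotation assigns the ten immune functional categories round-robin
    over the gene list. With ``out_dir`` set, the matrices, truth table,
    annotation and a manifest JSON are written there in the same TSV formats
    the loading functions consume.
    """
    config = scenario_config(seed)
    matrices, truth = generate(config)
    genes = list(truth.module_of)
    ann = GeneAnnotation({g: CATEGORIES[i % len(CATEGORIES)]
                          for i, g in enumerate(genes)})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .expression import write_expression
        files = {}
        for condition, matrix in matrices.items():
            name = f"expression_{condition}.tsv"
            write_expression(matrix, out / name)
            files[condition] = name
        truth.to_tsv(out / "truth_modules.tsv")
        ann.to_tsv(out / "annotation.tsv")
        manifest = {
            "seed": seed,
            "n_genes": config.n_genes,
            "n_samples_per_condition": config.n_samples_per_condition,
            "module_sizes": list(config.module_sizes),
            "rho_by_condition": {c: list(r) for c, r in SCENARIO_RHO.items()},
            "expression": files,
            "truth": "truth_modules.tsv",
            "annotation": "annotation.tsv",
        }
        with open(out / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2)
            handle.write("\n")
    return matrices, truth, ann
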