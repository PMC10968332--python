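"""Co-expression network construction from pairwise Pearson correlation.

All pairwise correlations among immune genes within one tissue group are
computed, each with a two-sided p-value from the t distribution, and an
undirected simple graph is built from the pairs passing the dual threshold
r >= r_min AND p < p_max (default r_min 0.95, p_max 0.05).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

#: Default dual-threshold values for edge creation.
DEFAULT_R_MIN = 0.95
DEFAULT_P_MAX = 0.05

CORRELATION_COLUMNS = ("gene_a", "gene_b", "r", "p", "n")


def corr_pvalue(r, n: int):
    """Two-sided p-value for a Pearson correlation under the null rho = 0.

    Uses the exact small-sample test: t = r*sqrt((n-2)/(1-r**2)) with n-2
    degrees of freedom. Perfect correlations (|r| = 1) give p = 0. Accepts a
    scalar or an array of correlations.
    """
    if n < 3:
        raise ValueError("p-value undefined for fewer than 3 samples")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    p = np.zeros_like(r_arr)
    interior = np.abs(r_arr) < 1.0
    t = r_arr[interior] * np.sqrt((n - 2) / (1.0 - r_arr[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p if p.ndim else float(p)


def pairwise_correlation(m: ExpressionMatrix) -> pd.DataFrame:
    """Pearson r and p for every unordered gene pair of a matrix.

    Genes with zero variance across samples are dropped beforehand with a
    warning (their correlation is undefined). Returns one row per unordered
    pair with the pair canonicalized so ``gene_a < gene_b`` lexicographically.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    values = m.values
    genes = np.asarray(m.gene_ids, dtype=object)
    variances = values.var(axis=1)
    keep = variances > 0
    if not np.all(keep):
        dropped = genes[~keep]
        logger.warning("dropping %d zero-variance gene(s): %s%s",
                       len(dropped), list(dropped[:5]),
                       "..." if len(dropped) > 5 else "")
        values, genes = values[keep], genes[keep]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes with non-zero variance")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    i, j = np.triu_indices(len(genes), k=1)
    r = corr[i, j]
    a, b = genes[i], genes[j]
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap]
    n = m.n_samples
    return pd.DataFrame({
        "gene_a": a, "gene_b": b,
        "r": r, "p": corr_pvalue(r, n),
        "n": np.full(len(r), n, dtype=int),
    })


def build_network(
    ct: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    ann: GeneAnnotation | None = None,
    absolute_r: bool = False,
) -> nx.Graph:
    """Build the undirected co-expression graph under the dual threshold.

    An edge is created for every pair with ``r >= r_min`` and ``p < p_max``.
    The threshold is sign-sensitive by default; ``absolute_r=True`` switches
    to ``|r| >= r_min``. Only genes incident to at least one edge become
    nodes; isolated genes are excluded. No multiple-testing correction is
    applied to the per-pair p-values (a deliberate, logged choice).
    """
    if not 0 < r_min <= 1:
        raise ValueError("r_min must be in (0, 1]")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    logger.info("dual threshold r >= %.3g and p < %.3g "
                "(no multiple-testing correction applied)", r_min, p_max)
    passing = np.abs(ct["r"]) >= r_min if absolute_r else ct["r"] >= r_min
    passing &= ct["p"] < p_max
    edges = ct.loc[passing, ["gene_a", "gene_b"]]
    net = nx.Graph()
    net.add_edges_from(edges.itertuples(index=False, name=None))
    universe = len(set(ct["gene_a"]) | set(ct["gene_b"]))
    logger.info("network: %d of %d genes connected, %d edges",
                net.number_of_nodes(), universe, net.number_of_edges())
    if ann is not None:
        for node in net.nodes:
            category = ann.get(node)
            if category is not None:
                net.nodes[node]["category"] = category
    return net


def write_correlation_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False, columns=list(CORRELATION_COLUMNS))


def read_correlation_table(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = set(CORRELATION_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"correlation table missing columns: {sorted(missing)}")
    return ct


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Two-column TSV edge list."""
    with open(path, "w") as handle:
        for u, v in sorted(map(sorted, net.edges())):
            handle.write(f"{u}\t{v}\n")


def write_sif(net: nx.Graph, path: str | Path,
              interaction: str = "co" ) -> None:
    """Cytoscape SIF: ``source  interaction  target`` per edge."""
    with open(path, "w") as handle:
        for u, v in sorted(map(sorted, net.edges())):
            handle.write(f"{u}\t{interaction}\t{v}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export; node ``category`` attributes are preserved."""
    nx.write_graphml(net, path)
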