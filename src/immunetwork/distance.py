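"""Between-network similarity from topology-profile vectors.

Each network is summarized by its 13-parameter topology profile and networks
are compared with Euclidean, Manhattan and cosine distances between the raw
profile vectors. Components are deliberately not rescaled by default — the
published comparisons of immune co-expression networks use the raw
parameters, where node and edge counts dominate — but z-scoring across the
profiles being compared is available for methodologically cleaner use.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .topology import PROFILE_FIELDS, TopologyProfile

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "manhattan", "cosine")

#: Packaged reference profiles: published topological parameters of the
#: immune co-expression networks built from GEO series GSE120622
#: (normal lung, LUAD and LUSC), in canonical 13-field order.
_REFERENCE_RESOURCE = "gse120622_profiles.json"


def profile_vector(p: TopologyProfile | Mapping[str, float] | np.ndarray,
                   ) -> np.ndarray:
    """The 13 profile values as a float vector in canonical field order."""
    if isinstance(p, TopologyProfile):
        return p.to_vector()
    if isinstance(p, Mapping):
        missing = set(PROFILE_FIELDS) - set(p)
        if missing:
            raise ValueError(f"profile missing fields: {sorted(missing)}")
        return np.array([p[name] for name in PROFILE_FIELDS], dtype=float)
    vec = np.asarray(p, dtype=float)
    if vec.shape != (len(PROFILE_FIELDS),):
        raise ValueError(
            f"profile vector must have length {len(PROFILE_FIELDS)}")
    return vec


def _resolve_nans(a: np.ndarray, b: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    nan_a, nan_b = np.isnan(a), np.isnan(b)
    if np.any(nan_a != nan_b):
        bad = [PROFILE_FIELDS[i] if len(a) == len(PROFILE_FIELDS) else i
               for i in np.flatnonzero(nan_a != nan_b)]
        raise ValueError(
            f"NaN present in only one profile at position(s) {bad}; "
            "cannot compare")
    both = nan_a & nan_b
    if np.any(both):
        logger.warning("skipping %d component(s) undefined (NaN) in both "
                       "profiles", int(both.sum()))
        return a[~both], b[~both]
    return a, b


def distance(a, b, metric: str = "euclidean") -> float:
    """Distance between two profile vectors.

    euclidean = sqrt(sum((a-b)^2)); manhattan = sum(|a-b|);
    cosine = 1 - a.b/(|a||b|). Components undefined (NaN) in *both* vectors
    are dropped with a warning; a NaN on one side only is an error, as is a
    zero-magnitude vector for the cosine metric.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    va, vb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape} vs {vb.shape}")
    va, vb = _resolve_nans(va, vb)
    if metric == "euclidean":
        return float(np.sqrt(np.sum((va - vb) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(va - vb)))
    norm_a, norm_b = np.linalg.norm(va), np.linalg.norm(vb)
    if norm_a == 0 or norm_b == 0:
        raise ValueError("cosine distance undefined for a zero-magnitude vector")
    return float(1.0 - np.dot(va, vb) / (norm_a * norm_b))


def compare_report(
    profiles: Mapping[str, TopologyProfile | Mapping[str, float] | np.ndarray],
    reference: str,
    metrics: tuple[str, ...] = METRICS,
    zscore: bool = False,
) -> pd.DataFrame:
    """Distance of every profile to a named reference, per metric.

    Returns a tidy frame with columns ``profile``, ``metric``, ``distance``,
    sorted by metric then ascending distance. With ``zscore=True`` each
    component is standardized (population SD) across the supplied profiles
    before distances are taken; constant components are zeroed.
    """
    if reference not in profiles:
        raise KeyError(f"unknown reference profile: {reference!r}")
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    names = list(profiles)
    vectors = {name: profile_vector(profiles[name]) for name in names}
    if zscore:
        stack = np.vstack([vectors[name] for name in names])
        mean, sd = stack.mean(axis=0), stack.std(axis=0)
        sd[sd == 0] = 1.0
        vectors = {name: (vec - mean) / sd for name, vec in vectors.items()}
    ref = vectors[reference]
    rows = [
        {"profile": name, "metric": metric,
         "distance": distance(vectors[name], ref, metric)}
        for metric in metrics
        for name in names if name != reference
    ]
    frame = pd.DataFrame(rows, columns=["profile", "metric", "distance"])
    return frame.sort_values(["metric", "distance"],
                             kind="stable").reset_index(drop=True)


def write_report(report: pd.DataFrame, path: str | Path,
                 format: str = "tsv") -> None:
    if format == "tsv":
        report.to_csv(path, sep="\t", index=False)
    elif format == "json":
        report.to_json(path, orient="records", indent=2)
    else:
        raise ValueError("format must be 'tsv' or 'json'")


def load_profiles_json(path: str | Path) -> dict[str, np.ndarray]:
    """Read a profiles JSON file: canonical labels plus named value lists."""
    with open(path) as handle:
        payload = json.load(handle)
    labels = payload.get("labels")
    if labels != list(PROFILE_FIELDS):
        raise ValueError("profiles file labels differ from the canonical "
                         f"field order {PROFILE_FIELDS}")
    out = {}
    for name, values in payload["profiles"].items():
        vec = np.asarray(values, dtype=float)
        if vec.shape != (len(PROFILE_FIELDS),):
            raise ValueError(f"profile {name!r} has wrong length")
        out[name] = vec
    return out


def load_reference_profiles() -> dict[str, np.ndarray]:
    """The bundled GSE120622 normal/LUAD/LUSC reference profile vectors."""
    source = resources.files("immunetwork.data") / _REFERENCE_RESOURCE
    with resources.as_file(source) as path:
        return load_profiles_json(path)
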