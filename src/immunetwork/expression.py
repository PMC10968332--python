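"""Expression-matrix handling for immune co-expression network analysis.

Loads genes × samples count matrices from TSV/CSV, normalizes them (CPM or
log2(CPM+1)), restricts them to an annotated immune-gene universe, and
down-samples the larger of two tissue groups so that correlation networks are
built from equal sample numbers per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The closed vocabulary of immune functional categories used for annotation.
CATEGORIES = (
    "adaptive immunity",
    "antigen presentation",
    "cytokines-chemokines",
    "complement",
    "hematopoiesis",
    "innate immunity",
    "leukocyte migration",
    "NK cell activity",
    "platelet activity",
    "signaling",
)

#: Recognised sample group labels.
GROUP_LABELS = ("normal", "LUAD", "LUSC", "other")

_SEPARATORS = {"tsv": "\t", "csv": ","}


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with optional group labels.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with sample IDs as columns. Values must
        be finite; raw counts are additionally expected to be non-negative.
    groups
        Optional mapping from sample ID to a group label
        (``normal``/``LUAD``/``LUSC``/``other``).
    """

    data: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dupes)[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dupes)[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        unknown = set(self.groups.values()) - set(GROUP_LABELS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)}")
        groups = {s: g for s, g in self.groups.items() if s in set(ids)}
        return ExpressionMatrix(self.data.loc[:, ids].copy(), groups)


class GeneAnnotation:
    """Map from gene ID to one of the ten immune functional categories."""

    def __init__(self, mapping: Mapping[str, str]):
        unknown = set(mapping.values()) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        self._mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._mapping

    def __getitem__(self, gene_id: str) -> str:
        return self._mapping[gene_id]

    def get(self, gene_id: str, default: str | None = None) -> str | None:
        return self._mapping.get(gene_id, default)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._mapping)

    def items(self):
        return self._mapping.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        """Read a two-column ``gene_id<TAB>category`` file."""
        frame = pd.read_csv(path, sep="\t", header=None,
                            names=["gene_id", "category"], dtype=str)
        if frame["gene_id"].duplicated().any():
            dupes = frame.loc[frame["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene IDs in annotation: {list(dupes)[:5]}")
        return cls(dict(zip(frame["gene_id"], frame["category"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self._mapping.items()).to_csv(
            path, sep="\t", header=False, index=False)


def _read_table(path: Path, sep: str) -> tuple[pd.DataFrame, list[str]]:
    """Read a delimited matrix; return the frame and the raw header tokens."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)
    frame = pd.read_csv(path, sep=sep, header=0, index_col=0,
                        float_precision="round_trip")
    # pandas silently renames duplicate header tokens; restore the raw names
    # so duplicate handling below sees the file as written.
    frame.columns = header[1:]
    return frame, header[1:]


def _raise_on_nonnumeric(frame: pd.DataFrame) -> pd.DataFrame:
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"malformed numeric cell at row {frame.index[row]!r}, "
            f"column {frame.columns[col]!r}: {frame.iat[row, col]!r}")
    if coerced.isna().to_numpy().any():
        row, col = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {frame.index[row]!r}, "
            f"column {frame.columns[col]!r}")
    return coerced


def load_expression(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "genes_as_rows",
    groups: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix into the canonical genes × samples form.

    The first column of the file holds row identifiers and the header row
    holds column identifiers. With ``orientation="samples_as_rows"`` the file
    is transposed after reading. Duplicate gene rows are collapsed by summing
    (count semantics) with a warning; duplicate sample IDs are an error.
    """
    if format not in _SEPARATORS:
        raise ValueError(f"format must be one of {sorted(_SEPARATORS)}")
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError("orientation must be genes_as_rows or samples_as_rows")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame, _ = _read_table(path, _SEPARATORS[format])
    if orientation == "samples_as_rows":
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dupes)[:5]}")
        frame = frame.T
    else:
        if pd.Index(frame.columns).has_duplicates:
            dupes = pd.Index(frame.columns)
            dupes = dupes[dupes.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dupes)[:5]}")
    frame = _raise_on_nonnumeric(frame)
    if frame.index.has_duplicates:
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by summation", n_dup)
        frame = frame.groupby(level=0, sort=False).sum()
    frame.index = frame.index.astype(str).rename("gene")
    frame.columns = frame.columns.astype(str).rename(None)
    return ExpressionMatrix(frame, dict(groups) if groups else {})


def write_expression(m: ExpressionMatrix, path: str | Path,
                     format: str = "tsv") -> None:
    """Write the matrix in the same layout ``load_expression`` reads.

    Full ``repr`` precision is used so a write/load round trip is
    bit-identical.
    """
    if format not in _SEPARATORS:
        raise ValueError(f"format must be one of {sorted(_SEPARATORS)}")
    m.data.to_csv(path, sep=_SEPARATORS[format], float_format=None)


def normalize(m: ExpressionMatrix, method: str = "log2_cpm_plus1") -> ExpressionMatrix:
    """Library-size normalization: ``none``, ``cpm`` or ``log2_cpm_plus1``.

    CPM rescales every sample (column) to sum to 1e6; the log variant applies
    log2(CPM + 1) element-wise, the usual variance-stabilizing transform
    before Pearson correlation of RNA-seq counts.
    """
    if method == "none":
        return m
    if method not in ("cpm", "log2_cpm_plus1"):
        raise ValueError(f"unknown normalization method: {method!r}")
    colsums = m.data.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    cpm = m.data.div(colsums, axis=1) * 1e6
    if method == "log2_cpm_plus1":
        cpm = np.log2(cpm + 1.0)
    return ExpressionMatrix(cpm, dict(m.groups))


def select_immune_genes(m: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Restrict the matrix to annotated immune genes, in annotation order."""
    present = [g for g in ann.gene_ids if g in set(m.gene_ids)]
    if not present:
        raise ValueError("no overlap between expression matrix and annotation")
    dropped = m.n_genes - len(present)
    logger.info("retained %d immune genes, dropped %d unannotated",
                len(present), dropped)
    return ExpressionMatrix(m.data.loc[present].copy(), dict(m.groups))


def match_groups(
    control: ExpressionMatrix,
    tumor: ExpressionMatrix,
    seed: int,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Equalize group sizes by seeded random down-sampling without replacement.

    The larger group is down-sampled to the size of the smaller; the
    selection is reproducible for a fixed seed and preserves the original
    sample order of the retained columns.
    """
    if control.n_samples == 0 or tumor.n_samples == 0:
        raise ValueError("both groups must be non-empty")
    if control.n_samples == tumor.n_samples:
        return control, tumor
    rng = np.random.default_rng(seed)

    def _downsample(m: ExpressionMatrix, size: int) -> ExpressionMatrix:
        chosen = rng.choice(m.n_samples, size=size, replace=False)
        keep = [m.sample_ids[i] for i in sorted(chosen)]
        logger.info("down-sampled %d -> %d samples", m.n_samples, size)
        return m.subset_samples(keep)

    if control.n_samples > tumor.n_samples:
        return _downsample(control, tumor.n_samples), tumor
    return control, _downsample(tumor, control.n_samples)


def load_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>group`` file."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["sample_id", "group"], dtype=str)
    unknown = set(frame["group"]) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return dict(zip(frame["sample_id"], frame["group"]))
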