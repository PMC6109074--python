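"""Gene-by-sample expression containers and their on-disk formats.

The package works on two thin wrappers around :class:`pandas.DataFrame`:

* :class:`CountMatrix` — raw non-negative read counts (genes in rows,
  samples in columns) together with a two-group condition labelling.
* :class:`LogExpressionMatrix` — normalized log2 expression values on the
  same gene/sample grid, carrying the labelling along.

On disk a count matrix is a plain TSV whose first column is ``gene_id`` and
whose header row holds the sample ids; the design is a two-column TSV
(``sample_id``, ``group``).  MatrixMarket input with sidecar id files is
also supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "LogExpressionMatrix",
    "read_counts_tsv",
    "read_counts_mtx",
    "read_design_tsv",
    "write_design_tsv",
]


def _as_group_series(group_labels, sample_ids: Sequence[str]) -> pd.Series:
    if isinstance(group_labels, pd.Series):
        ser = group_labels.astype(str)
    elif isinstance(group_labels, Mapping):
        ser = pd.Series({str(k): str(v) for k, v in group_labels.items()})
    else:  # positional sequence
        labels = [str(x) for x in group_labels]
        if len(labels) != len(sample_ids):
            raise ValidationError(
                f"{len(labels)} group labels for {len(sample_ids)} samples"
            )
        ser = pd.Series(labels, index=list(sample_ids))
    missing = [s for s in sample_ids if s not in ser.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    return ser.reindex(list(sample_ids))


def _check_two_groups(ser: pd.Series) -> tuple[str, str]:
    order = list(dict.fromkeys(ser.tolist()))  # first-appearance order
    if len(order) != 2:
        raise ValidationError(
            f"exactly two distinct group labels required, got {order!r}"
        )
    return order[0], order[1]


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) with a two-condition labelling.

    ``group_order`` is the pair of condition labels in order of first
    appearance along the sample axis; downstream fold changes are always
    ``mean(group_order[1]) - mean(group_order[0])``.
    """

    counts: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self):
        df = pd.DataFrame(self.counts)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = df.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("counts must be finite")
        if arr.size and (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = df
        self.group_labels = _as_group_series(self.group_labels, list(df.columns))
        self._group_order = _check_two_groups(self.group_labels)

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def group_order(self) -> tuple[str, str]:
        return self._group_order

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_mask(self) -> np.ndarray:
        """Boolean array over samples: True for the second group."""
        return (self.group_labels == self.group_order[1]).to_numpy()

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    def design(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.group_labels.to_numpy()}
        )


@dataclass
class LogExpressionMatrix:
    """Normalized log2 expression values on a gene x sample grid."""

    values: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self):
        df = pd.DataFrame(self.values)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self.values = df
        self.group_labels = _as_group_series(self.group_labels, list(df.columns))
        self._group_order = _check_two_groups(self.group_labels)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_order(self) -> tuple[str, str]:
        return self._group_order

    def group_mask(self) -> np.ndarray:
        return (self.group_labels == self.group_order[1]).to_numpy()

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# readers / writers

def read_design_tsv(path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and "group" in cols:
        df.columns = cols
    elif df.shape[1] >= 2:
        df = df.iloc[:, :2]
        df.columns = ["sample_id", "group"]
    else:
        raise ValidationError(f"design file {path} needs two columns")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy())


def write_design_tsv(matrix: CountMatrix, path) -> None:
    matrix.design().to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, design) -> CountMatrix:
    """Read the TSV count dialect (first column ``gene_id``).

    ``design`` may be a path to a design TSV, a mapping, or a Series.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValidationError(
            f"{path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    if isinstance(design, (str, Path)):
        design = read_design_tsv(design)
    return CountMatrix(df, design)


def read_counts_mtx(mtx_path, genes_path, samples_path, design) -> CountMatrix:
    """Read a MatrixMarket count matrix with one-id-per-line sidecars."""
    from scipy.io import mmread

    raw = mmread(mtx_path)
    mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x {len(samples)} samples"
        )
    if isinstance(design, (str, Path)):
        design = read_design_tsv(design)
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples), design)
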