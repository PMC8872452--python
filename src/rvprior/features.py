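"""Gene-level feature matrices and their pre-processing.

Each biological feature source (bulk developmental expression, reconstituted
gene-set membership probabilities, promoter-usage profiles, single-nucleus
expression averaged per cell type, ...) is a dense genes x features numeric
matrix. This module reads such matrices, reduces single-cell matrices to
per-cell-type averages, min-max normalizes score vectors, and aligns gene
rows across sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "reduce_by_group",
    "minmax_normalize",
    "align_genes",
]


def canonical_gene_ids(ids) -> pd.Index:
    """Exact-string gene ID harmonization: upper-case, strip whitespace."""
    return pd.Index([str(g).strip().upper() for g in ids], name="gene_id")


@dataclass
class FeatureMatrix:
    """A genes x features numeric matrix from a single source.

    ``data`` is a DataFrame indexed by canonical gene IDs with one column per
    feature; missing entries are NaN.
    """

    source: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = canonical_gene_ids(self.data.index)
        if self.data.index.has_duplicates:
            raise ValueError(f"duplicate gene ids in source {self.source!r}")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_names(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self):
        return self.data.shape


def read_feature_matrix(path, source: str, sep=None) -> FeatureMatrix:
    """Read a TSV/CSV matrix: first column gene IDs, header row feature names.

    Duplicate gene rows are collapsed by mean; non-numeric cells become NaN.
    Raises if the file yields no numeric feature columns.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns")
    num = raw.apply(pd.to_numeric, errors="coerce")
    if num.isna().all().all():
        raise ValueError(f"{path}: no numeric feature values")
    num.index = canonical_gene_ids(num.index)
    if num.index.has_duplicates:
        num = num.groupby(level=0, sort=False).mean()
    return FeatureMatrix(source=source, data=num)


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    # %.17g keeps write -> read exact for float64
    fm.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def reduce_by_group(cells_by_genes: pd.DataFrame, cell_group_labels, source: str = "grouped") -> FeatureMatrix:
    """Average a cells x genes matrix within cell groups (e.g. cell types).

    Dimensionality reduction for single-cell sources: one output feature per
    distinct group label, holding each gene's mean over that group's cells.
    Output columns are the sorted group labels.
    """
    labels = np.asarray(cell_group_labels)
    if len(labels) != cells_by_genes.shape[0]:
        raise ValueError(
            f"{len(labels)} group labels for {cells_by_genes.shape[0]} cell rows"
        )
    df = pd.DataFrame(cells_by_genes)
    means = df.groupby(labels, sort=True).mean()  # groups x genes
    out = means.T
    out.columns = [str(c) for c in out.columns]
    return FeatureMatrix(source=source, data=out)


def minmax_normalize(scores) -> np.ndarray:
    """Affinely rescale a vector to span [0, 1].

    Missing (NaN) entries are preserved; a constant vector maps to all 0.5
    (the uninformative midpoint, so a degenerate source neither dominates nor
    vanishes in a downstream average). All-missing input is an error.
    """
    x = np.asarray(scores, dtype=float).copy()
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("minmax_normalize: no finite values")
    lo = x[finite].min()
    hi = x[finite].max()
    if hi == lo:
        x[finite] = 0.5
        return x
    x[finite] = (x[finite] - lo) / (hi - lo)
    return x


def align_genes(matrices, universe):
    """Restrict each source to a gene universe, in universe order.

    Parameters
    ----------
    matrices : iterable of FeatureMatrix
    universe : sequence of gene IDs

    Returns
    -------
    aligned : dict source -> FeatureMatrix
        Only universe genes present in the source, ordered as the universe.
    coverage : DataFrame
        Columns ``source``, ``n_genes``, ``coverage`` (fraction of the
        universe found in the source).
    """
    uni = canonical_gene_ids(universe)
    if len(uni) == 0:
        raise ValueError("empty gene universe")
    uni = uni.drop_duplicates()
    aligned = {}
    rows = []
    for fm in matrices:
        keep = uni[uni.isin(fm.data.index)]
        aligned[fm.source] = FeatureMatrix(source=fm.source, data=fm.data.loc[keep])
        rows.append((fm.source, len(keep), len(keep) / len(uni)))
    coverage = pd.DataFrame(rows, columns=["source", "n_genes", "coverage"])
    return aligned, coverage
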