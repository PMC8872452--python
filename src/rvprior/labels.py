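"""Training labels from GWAS-locus candidate genes.

GWAS significant loci arrive as pre-resolved candidate lists: every gene in a
window around an index SNP, each carrying a posterior probability of being the
locus' risk gene (produced upstream by an integrative gene-prioritization
tool such as iRIGS). Two training classes are derived:

* **positives** (high-confidence risk genes, HRG): the top-posterior gene of
  each locus;
* **negatives** (local background genes, LBG): candidates whose posterior is
  strictly below the median posterior over *all* candidates.

The two classes feed the supervised risk-score model in
:mod:`rvprior.prediction`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrainingLabels",
    "select_training_labels",
    "read_candidates",
    "write_labels",
    "read_labels",
]

CANDIDATE_COLUMNS = ("gene_id", "locus_id", "posterior")


@dataclass(frozen=True)
class TrainingLabels:
    """Positive/negative gene sets plus the posterior cutoff used.

    Attributes
    ----------
    positives : frozenset of str
        Per-locus argmax-posterior genes (HRG).
    negatives : frozenset of str
        Genes with all posteriors strictly below ``median_posterior`` and not
        already positive (LBG).
    median_posterior : float
        Median posterior over all candidate entries; the negative cutoff.
    """

    positives: frozenset
    negatives: frozenset
    median_posterior: float

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "positive") for g in sorted(self.positives)]
        rows += [(g, "negative") for g in sorted(self.negatives)]
        return pd.DataFrame(rows, columns=["gene_id", "label"])


def _validate_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    if candidates is None or len(candidates) == 0:
        raise ValueError("candidate table is empty")
    missing = [c for c in CANDIDATE_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    df = candidates.loc[:, list(CANDIDATE_COLUMNS)].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["locus_id"] = df["locus_id"].astype(str)
    df["posterior"] = pd.to_numeric(df["posterior"], errors="raise")
    if df["posterior"].isna().any():
        raise ValueError("candidate posteriors contain missing values")
    if ((df["posterior"] < 0) | (df["posterior"] > 1)).any():
        raise ValueError("candidate posteriors must lie in [0, 1]")
    if df.duplicated(subset=["gene_id", "locus_id"]).any():
        raise ValueError("duplicate (gene_id, locus_id) pairs in candidate table")
    return df


def select_training_labels(candidates: pd.DataFrame) -> TrainingLabels:
    """Derive positive and negative training genes from locus candidates.

    Parameters
    ----------
    candidates : DataFrame
        Columns ``gene_id``, ``locus_id``, ``posterior``. Posteriors in
        [0, 1]; (gene, locus) pairs unique; every locus non-empty.

    Returns
    -------
    TrainingLabels
        Positives are the argmax-posterior gene of each locus (ties broken to
        the lexicographically smallest ``gene_id``). Negatives are genes whose
        posteriors are all strictly below the median posterior over the full
        candidate table, minus any gene that is positive in some locus. Genes
        exactly at the median stay unlabeled.
    """
    df = _validate_candidates(candidates)
    # per-locus top gene; sort makes the lexicographic tie-break explicit
    ordered = df.sort_values(
        ["locus_id", "posterior", "gene_id"], ascending=[True, False, True], kind="stable"
    )
    positives = frozenset(ordered.groupby("locus_id", sort=False).head(1)["gene_id"])
    median = float(np.median(df["posterior"].to_numpy()))
    below = df.groupby("gene_id")["posterior"].max() < median
    negatives = frozenset(below.index[below]) - positives
    return TrainingLabels(positives=positives, negatives=frozenset(negatives), median_posterior=median)


def read_candidates(path) -> pd.DataFrame:
    """Read a tab-separated candidate-gene table (gene_id, locus_id, posterior)."""
    df = pd.read_csv(path, sep="\t")
    return _validate_candidates(df)


def write_labels(labels: TrainingLabels, path) -> None:
    labels.to_frame().to_csv(path, sep="\t", index=False)


def read_labels(path) -> TrainingLabels:
    df = pd.read_csv(path, sep="\t")
    pos = frozenset(df.loc[df["label"] == "positive", "gene_id"].astype(str))
    neg = frozenset(df.loc[df["label"] == "negative", "gene_id"].astype(str))
    return TrainingLabels(positives=pos, negatives=neg, median_posterior=float("nan"))
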