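"""Gene-set enrichment of top-ranked predicted genes.

One-sided Fisher's exact tests of the top-N genes by ensemble score versus
the rest of the scored genome, with Bonferroni correction over the sets
tested. The exact p-value is the upper hypergeometric tail; odds ratios are
the sample (unconditional) a*d / (b*c), with the conditional MLE available
in verbose mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import canonical_gene_ids

__all__ = ["GeneSet", "fisher_enrichment", "read_gmt", "write_gmt"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def _one_sided_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """P(A >= a) under the hypergeometric null for the 2x2 table [[a,b],[c,d]]."""
    n_total = a + b + c + d
    n_set = a + c  # genes in the set (within the universe)
    n_top = a + b  # top-ranked genes
    return float(stats.hypergeom.sf(a - 1, n_total, n_set, n_top))


def fisher_enrichment(top_genes, gene_sets, universe, n_top=None, verbose=False) -> pd.DataFrame:
    """Enrichment of a top gene list in each gene set, versus the universe.

    Parameters
    ----------
    top_genes : ordered sequence of gene IDs (must lie within ``universe``)
    gene_sets : iterable of GeneSet
    universe : all scored genes ("rest of the genome" = universe minus top)
    n_top : int, optional
        Truncate ``top_genes`` to its first ``n_top`` entries.
    verbose : bool
        Also report the conditional-MLE odds ratio.

    Returns
    -------
    DataFrame with columns set, size, a, b, c, d, odds_ratio, p_one_sided,
    p_bonferroni (and odds_ratio_cmle when verbose). Bonferroni multiplies by
    the number of sets tested, capped at 1.
    """
    uni = set(canonical_gene_ids(universe))
    if not uni:
        raise ValueError("empty universe")
    top = list(dict.fromkeys(canonical_gene_ids(top_genes)))
    if n_top is not None:
        top = top[: int(n_top)]
    top = set(top)
    if not top:
        raise ValueError("empty top gene list")
    if not top <= uni:
        raise ValueError("top genes must be a subset of the universe")
    gene_sets = list(gene_sets)
    n_sets = len(gene_sets)
    rows = []
    for gs in gene_sets:
        members = {str(g).strip().upper() for g in gs.genes} & uni
        a = len(top & members)
        b = len(top) - a
        c = len(members) - a
        d = len(uni) - a - b - c
        if a == 0:
            odds = 0.0
        elif b * c == 0:
            odds = np.inf
        else:
            odds = a * d / (b * c)
        p = _one_sided_fisher_greater(a, b, c, d)
        row = {
            "set": gs.name,
            "size": len(members),
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "odds_ratio": odds,
            "p_one_sided": p,
            "p_bonferroni": min(1.0, p * n_sets),
        }
        if verbose:
            table = np.array([[a, b], [c, d]])
            row["odds_ratio_cmle"] = float(
                stats.contingency.odds_ratio(table, kind="conditional").statistic
            )
        rows.append(row)
    return pd.DataFrame(rows)


def read_gmt(path):
    """Parse a GMT file: one set per line — name, description, member genes.

    Duplicate genes within a line are deduplicated. Malformed lines (fewer
    than three tab-separated fields) raise with the line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, desc, *genes = parts
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=frozenset(genes), description=desc))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")
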