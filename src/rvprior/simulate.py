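"""Synthetic data with the statistical structure the framework assumes.

Three generators mirror the three real inputs:

* **loci** — GWAS-like loci, each containing one designated risk gene whose
  prioritization posterior is drawn from Beta(8, 2) and several non-risk
  candidates drawn from Beta(2, 8), plus locus-free background genes;
* **features** — per-source gene x feature matrices of standard normals, with
  a random half of each source's features shifted upward for risk genes by a
  standardized effect size;
* **p-values** — a two-groups model: each gene is non-null with probability
  logistic(intercept + slope * propensity), where the continuous risk
  propensity (Beta(8,2) for risk genes, Uniform(0,1) otherwise, so the
  non-null proportion genuinely spans its 2%-20% range across the genome)
  stands in for the imperfect biological signal a covariate can capture; a
  covariate correlated with the propensity is informative of the prior
  non-null probability without determining it. Null p-values are
  Uniform(0,1); non-null p-values are Beta(a, 1) with a < 1, which
  concentrates near zero and has the closed-form CDF P(p < t) = t**a.

Defaults give m = 5000 genes with the non-null proportion rising from 2% at
propensity 0 to 20% at propensity 1 — small enough for minute-scale suites,
rich enough for covariate weighting to find signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .features import FeatureMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_loci",
    "simulate_features",
    "simulate_rvas_pvalues",
    "score_replicate",
]


@dataclass
class SimConfig:
    """Generator parameters; defaults define the reference study conditions."""

    n_loci: int = 40
    genes_per_locus: int = 8
    n_background_genes: int = 4680
    n_sources: int = 4
    features_per_source: int = 20
    feature_effect_size: float = 2.0
    pi1_intercept: float = float(logit(0.02))
    pi1_slope: float = float(logit(0.20) - logit(0.02))
    alt_beta_a: float = 0.25
    include_null_source: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alt_beta_a < 1:
            raise ValueError("alt_beta_a must lie in (0, 1)")
        for name in ("n_loci", "genes_per_locus", "n_background_genes",
                     "n_sources", "features_per_source"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_genes(self) -> int:
        return self.n_loci * self.genes_per_locus + self.n_background_genes

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth per gene: risk status and continuous risk propensity."""

    genes: pd.DataFrame  # columns gene_id, is_risk, propensity
    config: SimConfig

    @property
    def gene_ids(self):
        return self.genes["gene_id"].to_numpy()

    @property
    def is_risk(self) -> np.ndarray:
        return self.genes["is_risk"].to_numpy(dtype=bool)

    @property
    def propensity(self) -> np.ndarray:
        return self.genes["propensity"].to_numpy(dtype=float)


def _rng(config: SimConfig, stage: int, rng=None):
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def simulate_loci(config: SimConfig, rng=None):
    """Draw locus candidate tables and the gene-level ground truth.

    Returns
    -------
    candidates : DataFrame (gene_id, locus_id, posterior)
        One designated risk gene per locus (posterior ~ Beta(8,2)) and
        ``genes_per_locus - 1`` non-risk candidates (posterior ~ Beta(2,8)).
    truth : SyntheticTruth
        Covers candidate and background genes; background genes carry no
        locus and are never risk genes.
    """
    rng = _rng(config, 0, rng)
    n_cand = config.n_loci * config.genes_per_locus
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    is_risk = np.zeros(config.n_genes, dtype=bool)

    rows = []
    g = 0
    for locus in range(config.n_loci):
        locus_id = f"L{locus:03d}"
        members = gene_ids[g : g + config.genes_per_locus]
        risk_gene = members[0]
        is_risk[g] = True
        rows.append((risk_gene, locus_id, rng.beta(8, 2)))
        for other in members[1:]:
            rows.append((other, locus_id, rng.beta(2, 8)))
        g += config.genes_per_locus
    candidates = pd.DataFrame(rows, columns=["gene_id", "locus_id", "posterior"])

    propensity = np.where(is_risk, rng.beta(8, 2, size=config.n_genes),
                          rng.random(config.n_genes))
    truth = SyntheticTruth(
        genes=pd.DataFrame({"gene_id": gene_ids, "is_risk": is_risk, "propensity": propensity}),
        config=config,
    )
    assert len(candidates) == n_cand
    return candidates, truth


def simulate_features(truth: SyntheticTruth, config: SimConfig, rng=None):
    """Per-source feature matrices with class-separated distributions.

    Features are i.i.d. standard normal; for risk genes a random half of each
    source's features is shifted by ``feature_effect_size`` standard
    deviations. With ``include_null_source`` the last source gets zero shift
    (an uninformative control).

    Returns dict source name -> FeatureMatrix over all truth genes.
    """
    rng = _rng(config, 1, rng)
    n_genes = len(truth.genes)
    out = {}
    for s in range(config.n_sources):
        name = f"SRC{s + 1}"
        X = rng.standard_normal((n_genes, config.features_per_source))
        effect = config.feature_effect_size
        if config.include_null_source and s == config.n_sources - 1:
            effect = 0.0
        shifted = rng.choice(
            config.features_per_source, size=max(1, config.features_per_source // 2), replace=False
        )
        if effect != 0.0:
            X[np.ix_(truth.is_risk, shifted)] += effect
        cols = [f"{name}_f{j}" for j in range(config.features_per_source)]
        out[name] = FeatureMatrix(source=name, data=pd.DataFrame(X, index=truth.gene_ids, columns=cols))
    return out


def simulate_rvas_pvalues(truth: SyntheticTruth, config: SimConfig, rng=None):
    """Two-groups gene-level p-values driven by the risk propensity.

    Each gene is non-null with probability
    ``clip(expit(pi1_intercept + pi1_slope * propensity), 0.001, 0.999)``;
    null p ~ Uniform(0,1), non-null p ~ Beta(alt_beta_a, 1).

    Returns
    -------
    table : DataFrame (gene_id, p)
    nonnull : ndarray of bool — ground truth for FDR/power scoring
    """
    rng = _rng(config, 2, rng)
    pi1 = np.clip(expit(config.pi1_intercept + config.pi1_slope * truth.propensity), 0.001, 0.999)
    nonnull = rng.random(len(pi1)) < pi1
    p = rng.random(len(pi1))
    n_alt = int(nonnull.sum())
    if n_alt:
        p[nonnull] = rng.beta(config.alt_beta_a, 1.0, size=n_alt)
    table = pd.DataFrame({"gene_id": truth.gene_ids, "p": p})
    return table, nonnull


def score_replicate(rejected, nonnull):
    """False discovery proportion and power of one rejection set.

    FDP = false rejections / max(1, rejections);
    power = true rejections / max(1, number of non-nulls).
    """
    rejected = np.asarray(rejected, dtype=bool)
    nonnull = np.asarray(nonnull, dtype=bool)
    if rejected.shape != nonnull.shape:
        raise ValueError("rejected and nonnull must have the same length")
    n_rej = int(rejected.sum())
    false_rej = int((rejected & ~nonnull).sum())
    true_rej = int((rejected & nonnull).sum())
    fdp = false_rej / max(1, n_rej)
    power = true_rej / max(1, int(nonnull.sum()))
    return fdp, power
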