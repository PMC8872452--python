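"""Covariate-adaptive FDR control: weighted Benjamini-Hochberg with cross-weighting.

Given m hypotheses with p-values p_1..p_m and a per-hypothesis covariate
X_1..X_m that is independent of the p-value under the null but informative of
the prior non-null probability (here: a gene-level risk score), power can be
gained over the plain Benjamini-Hochberg (BH) step-up rule by allocating more
FDR budget to hypotheses with favourable covariates.

The procedure implemented here:

1. hypotheses are binned into covariate strata of (near-)equal size, ordered
   by increasing covariate;
2. within each stratum, hypotheses are randomly split into k folds;
3. for each fold l, one weight per stratum is learned from the *other* k-1
   folds only (cross-weighting), by grid search maximizing the number of
   weighted-BH rejections of the training p-values at level alpha, under the
   budget constraint that weights average to one;
4. weighted p-values p_i / W(X_i) enter a single BH pass at level alpha.

Because the weight applied to hypothesis i never sees p_i, the weighting
cannot overfit the p-values and FDR control is preserved; because weights are
normalized to mean one over the hypotheses they apply to, the weighted BH
pass remains a valid FDR procedure.

All of this is implemented directly (no multiple-testing library is called):
the decision rule itself is the package's core.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "bh_adjust",
    "bh_rejections",
    "qvalues_to_pvalues",
    "assign_strata",
    "learn_stratum_weights",
    "IndependentHypothesisWeighting",
    "ihw",
    "shuffled_covariate_control",
    "stratified_pvalue_histogram",
    "auto_n_bins",
    "read_hypothesis_table",
]

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
#: smallest positive double; p-values of exactly 0 are clipped here before weighting
TINY_P = np.nextafter(0.0, 1.0)


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.isnan(p).any():
        raise ValueError("p contains NaN; drop missing rows first")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """BH-adjusted p-values: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1.

    Accepts weighted p-values larger than 1 (they adjust to 1).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def bh_rejections(p, alpha: float):
    """Benjamini-Hochberg step-up procedure at level alpha.

    Rejects hypothesis i iff p_i <= p_(k*) where
    k* = max{k : p_(k) <= k * alpha / m}.

    Returns
    -------
    adjusted_p : ndarray
    rejected : ndarray of bool
    """
    p = _check_p(p)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = p.size
    ps = np.sort(p, kind="stable")
    ok = ps <= alpha * np.arange(1, m + 1) / m
    kstar = int(np.max(np.flatnonzero(ok))) + 1 if ok.any() else 0
    rejected = p <= ps[kstar - 1] if kstar else np.zeros(m, dtype=bool)
    return bh_adjust(p), rejected


def _count_bh_rejections_rows(wp: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized k* for each row of a (candidates x m) weighted-p matrix."""
    m = wp.shape[1]
    s = np.sort(wp, axis=1)
    ok = s <= alpha * np.arange(1, m + 1) / m
    any_ok = ok.any(axis=1)
    kstar = m - np.argmax(ok[:, ::-1], axis=1)
    return np.where(any_ok, kstar, 0)


def qvalues_to_pvalues(q) -> np.ndarray:
    """Invert BH adjustment: recover p-values whose BH q-values equal ``q``.

    Sorts q ascending (stable), repairs monotonicity by a running maximum,
    sets p_(i) = q_(i) * i / m, and restores the original order. BH-adjusting
    the result reproduces the (monotone-repaired) input, because
    min_{j>=i} q_(j) = q_(i) for a non-decreasing sequence.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q must be a non-empty 1-d vector")
    if np.isnan(q).any() or (q < 0).any() or (q > 1).any():
        raise ValueError("q-values must lie in [0, 1]")
    m = q.size
    order = np.argsort(q, kind="stable")
    qs = np.maximum.accumulate(q[order])
    p_sorted = qs * np.arange(1, m + 1) / m
    out = np.empty(m)
    out[order] = p_sorted
    return out


def assign_strata(x, n_bins: int) -> np.ndarray:
    """Quantile-bin a covariate into ``n_bins`` near-equal strata.

    Ties are broken by stable rank so stratum sizes differ by at most one;
    stratum index increases with the covariate.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariates must be finite")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    m = x.size
    if n_bins > m:
        raise ValueError(f"n_bins={n_bins} exceeds number of hypotheses m={m}")
    order = np.argsort(x, kind="stable")
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(m)
    return ((rank * n_bins) // m).astype(np.int64)


def auto_n_bins(m: int) -> int:
    """Default stratum count: ~1500 hypotheses per stratum, between 1 and 10."""
    return max(1, min(10, m // 1500))


def _normalize_masses(masses: np.ndarray, counts: np.ndarray):
    """Rescale raw per-stratum masses so sum_g n_g w_g = sum_g n_g."""
    denom = masses @ counts
    scale = np.where(denom > 0, counts.sum() / np.where(denom > 0, denom, 1.0), np.nan)
    return masses * scale[:, None]


def learn_stratum_weights(
    training_p_by_stratum,
    alpha: float,
    weight_grid=DEFAULT_WEIGHT_GRID,
    tv_lambda=None,
    random_state=0,
) -> np.ndarray:
    """Grid-search per-stratum weights maximizing training rejections.

    Candidate weight vectors take raw masses per stratum from ``weight_grid``
    and are rescaled to the budget sum_g n_g w_g = sum_g n_g. The candidate
    maximizing the number of weighted-BH rejections of the pooled training
    p-values at level ``alpha`` wins; ties go to the vector closest to uniform
    in squared distance. With ``tv_lambda`` set, candidates whose total
    variation sum_g |w_{g+1} - w_g| exceeds it are excluded.

    Search is exhaustive for up to 5 strata and coordinate ascent with 3
    random restarts beyond that.

    Returns the budget-normalized weight vector (one weight per stratum).
    """
    strata = [np.asarray(s, dtype=float) for s in training_p_by_stratum]
    G = len(strata)
    if G == 0:
        raise ValueError("need at least one stratum")
    for g, s in enumerate(strata):
        if s.size == 0:
            raise ValueError(f"stratum {g} has no training p-values")
    counts = np.array([s.size for s in strata], dtype=float)
    p = np.concatenate(strata)
    p = np.where(p == 0.0, TINY_P, p)
    stratum_of = np.concatenate([np.full(s.size, g, dtype=int) for g, s in enumerate(strata)])
    grid = np.asarray(sorted(set(float(v) for v in weight_grid)))
    if (grid < 0).any():
        raise ValueError("weight grid must be non-negative")

    def evaluate(mass_matrix: np.ndarray):
        """(rejections, sq-dist-to-uniform, normalized weights) per candidate row."""
        w = _normalize_masses(mass_matrix, counts)
        valid = np.isfinite(w).all(axis=1)
        if tv_lambda is not None and G > 1:
            tv = np.abs(np.diff(w, axis=1)).sum(axis=1)
            valid &= tv <= tv_lambda + 1e-12
        rej = np.full(len(w), -1)
        vi = np.flatnonzero(valid)
        # chunk candidates to bound the candidates x m workspace
        chunk = max(1, int(2e7) // max(1, p.size))
        for start in range(0, vi.size, chunk):
            block = vi[start : start + chunk]
            with np.errstate(divide="ignore"):
                wp = p[None, :] / w[block][:, stratum_of]
            rej[block] = _count_bh_rejections_rows(wp, alpha)
        dist = np.square(w - 1.0).sum(axis=1)
        return rej, dist, w

    def pick_best(mass_matrix):
        """Best candidate by (rejections desc, distance-to-uniform asc, order)."""
        rej, dist, w = evaluate(mass_matrix)
        best = np.lexsort((np.arange(len(w)), dist, -rej))[0]
        if rej[best] < 0:
            raise ValueError("no valid weight candidate (check tv_lambda)")
        return best, (int(rej[best]), -dist[best]), w[best]

    if G <= 5:
        masses = np.array(list(itertools.product(grid, repeat=G)))
        masses = masses[masses.sum(axis=1) > 0]
        _, _, w_best = pick_best(masses)
        return w_best

    # coordinate ascent with restarts for many strata
    rng = np.random.default_rng(random_state)
    starts = [np.ones(G)] + [rng.choice(grid[grid > 0], size=G) for _ in range(3)]
    overall_key, overall_w = None, None
    for start in starts:
        cur = np.asarray(start, dtype=float)
        _, cur_key, _ = pick_best(cur[None, :])
        for _ in range(20):  # sweeps until stable
            changed = False
            for g in range(G):
                cands = np.tile(cur, (grid.size, 1))
                cands[:, g] = grid
                cands = cands[cands.sum(axis=1) > 0]
                bi, key, _ = pick_best(cands)
                if key > cur_key:
                    cur = cands[bi]
                    cur_key = key
                    changed = True
            if not changed:
                break
        _, key, w = pick_best(cur[None, :])
        if overall_key is None or key > overall_key:
            overall_key, overall_w = key, w
    return overall_w


class IndependentHypothesisWeighting(BaseEstimator):
    """Covariate-stratified weighted BH with cross-weighting.

    Parameters
    ----------
    alpha : float, default 0.1
        Target FDR level.
    n_bins : int or 'auto', default 'auto'
        Number of covariate strata; 'auto' targets ~1500 hypotheses per
        stratum, capped at 10. ``n_bins=1`` reduces exactly to plain BH.
    n_folds : int, default 5
        Cross-weighting folds; fold l's weights are learned from the other
        folds' p-values only.
    weight_grid : tuple of float
        Raw per-stratum masses searched (budget-normalized afterwards).
    tv_lambda : float or None
        Optional total-variation bound on the weight vector (off by default).
    random_state : int or None
        Seed for the stratified fold split.

    Attributes
    ----------
    m_ : int; n_bins_ : int (after auto/fallback resolution)
    stratum_of_, fold_of_ : ndarray per hypothesis
    weights_ : ndarray (n_folds, n_bins) — weight applied to each
        (fold, stratum) cell, rescaled to mean exactly 1 over each fold
    weight_of_ : ndarray per hypothesis
    weighted_p_, adjusted_p_ : ndarray
    rejected_ : ndarray of bool
    threshold_ : float — realized weighted-p cutoff t-hat (0 if no rejection)
    n_rejected_ : int
    """

    def __init__(
        self,
        alpha: float = 0.1,
        n_bins="auto",
        n_folds: int = 5,
        weight_grid=DEFAULT_WEIGHT_GRID,
        tv_lambda=None,
        random_state=None,
    ):
        self.alpha = alpha
        self.n_bins = n_bins
        self.n_folds = n_folds
        self.weight_grid = weight_grid
        self.tv_lambda = tv_lambda
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _resolve_bins(self, m: int) -> int:
        n_bins = auto_n_bins(m) if self.n_bins == "auto" else int(self.n_bins)
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1 or 'auto'")
        if n_bins > 1 and m < self.n_folds * n_bins:
            logger.warning(
                "m=%d too small for %d strata x %d folds; falling back to one stratum",
                m, n_bins, self.n_folds,
            )
            n_bins = 1
        return n_bins

    def fit(self, pvalues, covariates):
        """Learn fold weights and run the weighted BH pass.

        Parameters
        ----------
        pvalues : 1-d array in [0, 1] (no NaN)
        covariates : 1-d finite array, same length
        """
        p = _check_p(pvalues)
        x = np.asarray(covariates, dtype=float)
        if x.shape != p.shape:
            raise ValueError("pvalues and covariates must have the same length")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        m = p.size
        n_bins = self._resolve_bins(m)
        if n_bins > 1 and np.unique(x).size == 1:
            logger.info("constant covariate carries no information; using a single stratum")
            n_bins = 1
        strata = assign_strata(x, n_bins)
        sizes = np.bincount(strata, minlength=n_bins)
        if n_bins > 1 and sizes.min() < self.n_folds:
            logger.warning(
                "smallest stratum (%d) below n_folds=%d; falling back to one stratum",
                sizes.min(), self.n_folds,
            )
            n_bins = 1
            strata = np.zeros(m, dtype=np.int64)

        # stratified, seeded fold split
        rng = np.random.default_rng(self.random_state)
        folds = np.empty(m, dtype=np.int64)
        for g in range(n_bins):
            idx = np.flatnonzero(strata == g)
            perm = rng.permutation(idx)
            folds[perm] = np.arange(perm.size) % self.n_folds

        p_clipped = np.where(p == 0.0, TINY_P, p)
        weights = np.ones((self.n_folds, n_bins))
        if n_bins > 1:
            for l in range(self.n_folds):
                train = folds != l
                train_by_stratum = [p_clipped[train & (strata == g)] for g in range(n_bins)]
                w = learn_stratum_weights(
                    train_by_stratum,
                    self.alpha,
                    weight_grid=self.weight_grid,
                    tv_lambda=self.tv_lambda,
                    random_state=0,
                )
                # rescale to the held-out fold: mean weight over fold l == 1.
                # Uses only the fold's stratum counts (covariate information),
                # never its p-values, so cross-weighting independence holds.
                hold = folds == l
                hold_counts = np.bincount(strata[hold], minlength=n_bins)
                denom = w @ hold_counts
                weights[l] = w * (hold_counts.sum() / denom) if denom > 0 else 1.0

        weight_of = weights[folds, strata]
        with np.errstate(divide="ignore"):
            weighted_p = np.where(weight_of > 0, p_clipped / np.where(weight_of > 0, weight_of, 1.0), np.inf)
        adjusted, rejected = _weighted_bh_pass(weighted_p, self.alpha)

        self.m_ = m
        self.n_bins_ = n_bins
        self.stratum_of_ = strata
        self.fold_of_ = folds
        self.weights_ = weights
        self.weight_of_ = weight_of
        self.weighted_p_ = weighted_p
        self.adjusted_p_ = adjusted
        self.rejected_ = rejected
        self.n_rejected_ = int(rejected.sum())
        self.threshold_ = float(weighted_p[rejected].max()) if rejected.any() else 0.0
        return self

    def result_frame(self, gene_ids=None, pvalues=None, covariates=None) -> pd.DataFrame:
        check_is_fitted(self, "rejected_")
        df = pd.DataFrame(
            {
                "stratum": self.stratum_of_,
                "fold": self.fold_of_,
                "weight": self.weight_of_,
                "weighted_p": self.weighted_p_,
                "adjusted_p": self.adjusted_p_,
                "rejected": self.rejected_,
            }
        )
        if covariates is not None:
            df.insert(0, "covariate", np.asarray(covariates, dtype=float))
        if pvalues is not None:
            df.insert(0, "p", np.asarray(pvalues, dtype=float))
        if gene_ids is not None:
            df.insert(0, "gene_id", list(gene_ids))
        return df


def _weighted_bh_pass(weighted_p: np.ndarray, alpha: float):
    """Single BH pass over (possibly infinite) weighted p-values."""
    m = weighted_p.size
    finite = np.where(np.isfinite(weighted_p), weighted_p, 2.0)  # >1 never rejects
    ws = np.sort(finite, kind="stable")
    ok = ws <= alpha * np.arange(1, m + 1) / m
    kstar = int(np.max(np.flatnonzero(ok))) + 1 if ok.any() else 0
    rejected = finite <= ws[kstar - 1] if kstar else np.zeros(m, dtype=bool)
    adjusted = bh_adjust(finite)
    return adjusted, rejected


def ihw(
    pvalues,
    covariates,
    alpha: float = 0.1,
    n_bins="auto",
    n_folds: int = 5,
    weight_grid=DEFAULT_WEIGHT_GRID,
    tv_lambda=None,
    seed=None,
) -> IndependentHypothesisWeighting:
    """Functional wrapper: fit :class:`IndependentHypothesisWeighting`.

    Rows with missing p-values are dropped with a logged count before
    fitting (the fitted attributes then refer to the retained rows).
    """
    p = np.asarray(pvalues, dtype=float)
    x = np.asarray(covariates, dtype=float)
    keep = ~np.isnan(p)
    if (~keep).any():
        logger.warning("dropping %d hypotheses with missing p-values", int((~keep).sum()))
        p, x = p[keep], x[keep]
    est = IndependentHypothesisWeighting(
        alpha=alpha,
        n_bins=n_bins,
        n_folds=n_folds,
        weight_grid=weight_grid,
        tv_lambda=tv_lambda,
        random_state=seed,
    )
    return est.fit(p, x)


def shuffled_covariate_control(
    pvalues, covariates, n_shuffles: int, alpha: float = 0.1, seed=None, **ihw_kwargs
) -> np.ndarray:
    """Rejections of IHW run on randomly permuted covariates.

    A well-behaved weighting procedure should, with an uninformative
    (shuffled) covariate, reject about as many hypotheses as plain BH —
    neither gaining nor losing power. Returns one rejection count per shuffle.
    """
    p = np.asarray(pvalues, dtype=float)
    x = np.asarray(covariates, dtype=float)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(int(n_shuffles)):
        perm = rng.permutation(x.size)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = ihw(p, x[perm], alpha=alpha, seed=sub_seed, **ihw_kwargs)
        counts.append(res.n_rejected_)
    return np.asarray(counts, dtype=int)


def stratified_pvalue_histogram(
    pvalues, covariates, quantile_breaks=(0.33, 0.67), bin_width: float = 0.05
):
    """P-value histograms within covariate groups (diagnostic of informativeness).

    Hypotheses are split at the covariate's given quantiles into ``low``,
    ``medium`` and ``high`` groups. An informative covariate shows a growing
    spike of near-zero p-values from the low to the high group; a flat first
    bin across groups indicates no usable prior signal.

    Returns
    -------
    counts : DataFrame
        Rows low/medium/high, one column per p-value bin.
    first_bin : Series
        Count of p < ``bin_width`` per group.
    """
    p = _check_p(pvalues)
    x = np.asarray(covariates, dtype=float)
    lo_q, hi_q = np.quantile(x, quantile_breaks)
    group = np.where(x < lo_q, "low", np.where(x > hi_q, "high", "medium"))
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    rows = {}
    for name in ("low", "medium", "high"):
        rows[name], _ = np.histogram(p[group == name], bins=edges)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=[
        f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(len(edges) - 1)
    ])
    first_bin = counts.iloc[:, 0].rename("n_p_below_bin_width")
    return counts, first_bin


def plot_stratified_histogram(pvalues, covariates, path, **kwargs):
    """Save the three-group p-value histogram panel to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, _ = stratified_pvalue_histogram(pvalues, covariates, **kwargs)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
    centers = np.arange(counts.shape[1])
    for ax, name in zip(axes, ("low", "medium", "high")):
        ax.bar(centers, counts.loc[name].to_numpy(), width=1.0)
        ax.set_title(f"{name} score")
        ax.set_xlabel("p-value bin")
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def read_hypothesis_table(path, p_column: str = "p", from_qvalues: bool = False) -> pd.DataFrame:
    """Read a gene-level hypothesis table (TSV with gene_id + p or q column).

    With ``from_qvalues=True`` the column is treated as BH q-values and
    inverted to p-values via :func:`qvalues_to_pvalues`.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("hypothesis table needs a gene_id column")
    if p_column not in df.columns:
        raise ValueError(f"hypothesis table has no column {p_column!r}")
    vals = pd.to_numeric(df[p_column], errors="coerce").to_numpy()
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str)})
    out["p"] = qvalues_to_pvalues(vals) if from_qvalues else vals
    return out
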