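"""Gene-level disease-risk scoring with downsampled random-forest ensembles.

The training set is highly imbalanced (one high-confidence risk gene versus
several background genes per locus), so each of ``n_repeats`` repeats
downsamples the negatives to the number of positives, tunes a random forest
by ``n_cv_folds``-fold cross-validation on the balanced set, refits the
winning configuration on the whole balanced set and scores every gene in the
feature matrix. The final per-source score is the mean class probability over
repeats; per-source scores are min-max normalized and averaged into an
ensemble score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix, minmax_normalize
from .labels import TrainingLabels

__all__ = [
    "ModelConfig",
    "GeneRiskClassifier",
    "train_and_score",
    "ensemble_score",
    "cross_validated_auc",
]

logger = logging.getLogger(__name__)

#: hyperparameter grid for the number of features tried per split
DEFAULT_MAX_FEATURES_GRID = ("sqrt", 1 / 3, 1 / 2)


@dataclass
class ModelConfig:
    """Training configuration: forest size, repeat count, CV folds, seed."""

    n_trees: int = 3000
    n_repeats: int = 100
    n_cv_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_cv_folds < 2:
            raise ValueError("n_cv_folds must be >= 2")


def cross_validated_auc(true_labels, scores) -> float:
    """Area under the ROC curve: P(random positive outranks random negative).

    Ties receive half credit. Raises on single-class input.
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


class GeneRiskClassifier(ClassifierMixin, BaseEstimator):
    """Repeat-downsampled, CV-tuned random-forest risk scorer.

    Parameters
    ----------
    n_trees : int, default 3000
        Trees per forest.
    n_repeats : int, default 100
        Balanced-downsampling repeats; the final score averages over them.
    n_cv_folds : int, default 3
        Stratified CV folds used within each repeat to pick ``max_features``.
    max_features_grid : tuple, default ('sqrt', 1/3, 1/2)
        Candidate fractions of features tried per split, compared by mean
        held-out AUC; the winner is refit on the full balanced set.
    random_state : int or None
        Master seed; repeat ``r`` draws from an independent child stream.

    Attributes
    ----------
    classes_ : ndarray
        ``[0, 1]``.
    models_ : list of RandomForestClassifier
        One refit forest per repeat.
    repeat_aucs_ : ndarray, shape (n_repeats,)
        Mean held-out AUC of each repeat's selected configuration.
    cv_results_ : DataFrame
        Columns repeat, fold, max_features, auc for every fitted fold model.
    medians_ : ndarray
        Per-feature medians over the training genes, used to impute missing
        values at fit and predict time.
    """

    def __init__(
        self,
        n_trees: int = 3000,
        n_repeats: int = 100,
        n_cv_folds: int = 3,
        max_features_grid=DEFAULT_MAX_FEATURES_GRID,
        random_state=None,
    ):
        self.n_trees = n_trees
        self.n_repeats = n_repeats
        self.n_cv_folds = n_cv_folds
        self.max_features_grid = max_features_grid
        self.random_state = random_state

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float)
        if np.isnan(X).any():
            idx = np.where(np.isnan(X))
            X[idx] = self.medians_[idx[1]]
        return X

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (genes x features)")
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        if n_pos < 2 or n_neg < 2:
            raise ValueError(f"need >=2 genes per class, got {n_pos} positives / {n_neg} negatives")

        # imputation parameters learned on training genes only
        with np.errstate(all="ignore"):
            self.medians_ = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isfinite(self.medians_), self.medians_, 0.0)
        X = self._impute(X)

        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        n_bal = min(n_pos, n_neg)

        master = np.random.SeedSequence(self.random_state)
        children = master.spawn(self.n_repeats)

        self.models_ = []
        repeat_aucs = []
        cv_rows = []
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            # balanced set: all positives, negatives downsampled w/o replacement
            neg_sub = rng.choice(neg_idx, size=n_bal, replace=False)
            pos_sub = pos_idx if n_pos == n_bal else rng.choice(pos_idx, size=n_bal, replace=False)
            sel = np.concatenate([pos_sub, neg_sub])
            Xb, yb = X[sel], y[sel]

            seeds = rng.integers(0, 2**31 - 1, size=len(self.max_features_grid) + 2)
            skf = StratifiedKFold(
                n_splits=self.n_cv_folds, shuffle=True, random_state=int(seeds[-1])
            )
            splits = list(skf.split(Xb, yb))
            best = None
            for gi, mf in enumerate(self.max_features_grid):
                fold_aucs = []
                for fi, (tr, te) in enumerate(splits):
                    clf = RandomForestClassifier(
                        n_estimators=self.n_trees,
                        max_features=mf,
                        random_state=int(seeds[gi]),
                        n_jobs=1,
                    ).fit(Xb[tr], yb[tr])
                    prob = clf.predict_proba(Xb[te])[:, list(clf.classes_).index(1)]
                    try:
                        auc = cross_validated_auc(yb[te], prob)
                    except ValueError:  # degenerate fold with one class
                        auc = np.nan
                    fold_aucs.append(auc)
                    cv_rows.append((r, fi, mf, auc))
                mean_auc = float(np.nanmean(fold_aucs))
                if best is None or mean_auc > best[0]:
                    best = (mean_auc, mf, int(seeds[gi]))
            repeat_aucs.append(best[0])
            final = RandomForestClassifier(
                n_estimators=self.n_trees,
                max_features=best[1],
                random_state=best[2],
                n_jobs=1,
            ).fit(Xb, yb)
            self.models_.append(final)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.repeat_aucs_ = np.asarray(repeat_aucs)
        self.cv_results_ = pd.DataFrame(cv_rows, columns=["repeat", "fold", "max_features", "auc"])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "models_")
        X = self._impute(np.asarray(X, dtype=float))
        p1 = np.zeros(X.shape[0])
        for m in self.models_:
            p1 += m.predict_proba(X)[:, list(m.classes_).index(1)]
        p1 /= len(self.models_)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_and_score(features: FeatureMatrix, labels: TrainingLabels, config: ModelConfig):
    """Fit the repeat-downsampled forest on one source and score all genes.

    Returns
    -------
    scores : Series
        Mean class-probability score in [0, 1] for every gene in ``features``.
    repeat_aucs : ndarray
        Mean held-out AUC per repeat.
    """
    genes = features.data.index
    pos = [g for g in genes if g in labels.positives]
    neg = [g for g in genes if g in labels.negatives]
    if not pos and not neg:
        raise ValueError(f"no labeled genes present in source {features.source!r}")
    train_genes = pos + neg
    y = np.array([1] * len(pos) + [0] * len(neg))
    clf = GeneRiskClassifier(
        n_trees=config.n_trees,
        n_repeats=config.n_repeats,
        n_cv_folds=config.n_cv_folds,
        random_state=config.seed,
    )
    clf.fit(features.data.loc[train_genes].to_numpy(dtype=float), y)
    scores = pd.Series(
        clf.predict_proba(features.values)[:, 1], index=genes, name=f"score_{features.source}"
    )
    logger.info(
        "source %s: %d pos / %d neg, mean CV AUC %.3f",
        features.source, len(pos), len(neg), float(np.nanmean(clf.repeat_aucs_)),
    )
    return scores, clf.repeat_aucs_


def ensemble_score(per_source_scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each source's genome-wide scores and average them.

    Parameters
    ----------
    per_source_scores : DataFrame
        Genes x sources; NaN where a gene is absent from a source.

    Returns
    -------
    DataFrame
        The normalized per-source columns plus an ``ensemble`` column: the
        per-gene mean over sources with a score. Genes with no source score
        keep NaN ensemble and are counted in a warning.
    """
    if per_source_scores.shape[1] == 0:
        raise ValueError("need at least one source")
    norm = pd.DataFrame(np.column_stack([minmax_normalize(per_source_scores[c].to_numpy())
                                         for c in per_source_scores.columns]),
                        index=per_source_scores.index, columns=per_source_scores.columns)
    out = norm.copy()
    out["ensemble"] = norm.mean(axis=1, skipna=True)
    n_missing = int(out["ensemble"].isna().sum())
    if n_missing:
        logger.warning("%d genes have no score from any source; ensemble left missing", n_missing)
    return out
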