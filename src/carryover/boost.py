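"""SAMME multi-class adaptive boosting of phenology features.

Predicts the reproductive-performance category of a bird-season
(SUCCESS / FAIL / SKIP) from annual-cycle event dates.  The boosting loop is
the multi-class SAMME generalisation of AdaBoost: at round m a depth-capped
decision tree is fitted to the weighted sample, its weighted misclassification
err_m gives the learner weight

    alpha_m = ln((1 - err_m) / err_m) + ln(K - 1),

misclassified weights are multiplied by exp(alpha_m) and renormalised, and
rounds no better than K-class random guessing (err_m >= (K-1)/K) are
discarded, stopping the loop.  With K = 2 the extra ln(K-1) term vanishes and
the scheme is exactly classical AdaBoost.

Feature importances are the alpha-weighted, normalised split-gain sums of the
weak learners.  Model assessment uses stratified k-fold cross-validation and
a within-sex label-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .config import FEATURE_REGISTRY

#: cap on a learner weight when a round classifies perfectly
ALPHA_CAP = np.log(1e10)


class SammeClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class AdaBoost (SAMME) over depth-capped CART trees.

    Parameters
    ----------
    n_estimators : int
        Maximum boosting rounds (early stop on a perfect or a no-better-
        than-chance round).
    max_depth : int
        Depth of the weak learners; 1 gives decision stumps.
    random_state : int or None
        Seeds the (deterministic given the seed) tree tie-breaking.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels (ties in the final vote break toward the
        earliest entry).
    estimators_, estimator_weights_ : list, ndarray
        Fitted weak learners and their alpha_m.
    feature_importances_ : ndarray
        Alpha-weighted split-gain importances, normalised to sum to 1.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 1, random_state=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.isnan(X).all(axis=0).any():
            raise ValueError("a feature column is entirely missing")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes to boost")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        n = len(y)
        self.n_features_in_ = X.shape[1]
        w = np.full(n, 1.0 / n)
        rng = np.random.default_rng(self.random_state)
        self.estimators_: list[DecisionTreeClassifier] = []
        alphas: list[float] = []
        for _ in range(int(self.n_estimators)):
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X, y_idx, sample_weight=w)
            pred = tree.predict(X)
            mis = pred != y_idx
            err = float(w[mis].sum())
            if err >= (K - 1) / K - 1e-12:
                break  # no better than chance: discard round, stop
            if err <= 0:
                self.estimators_.append(tree)
                alphas.append(ALPHA_CAP + np.log(K - 1))
                break  # perfect round dominates the vote
            alpha = np.log((1 - err) / err) + np.log(K - 1)
            self.estimators_.append(tree)
            alphas.append(alpha)
            w = w * np.exp(alpha * mis)
            w = w / w.sum()
        if not self.estimators_:
            # even the first round was at chance: keep it with zero weight so
            # prediction still works (majority-class behaviour of the stump)
            self.estimators_.append(tree)
            alphas.append(0.0)
        self.estimator_weights_ = np.asarray(alphas)
        self.m_rounds_ = len(self.estimators_)

        imp = np.zeros(X.shape[1])
        for tree, a in zip(self.estimators_, self.estimator_weights_):
            imp += max(a, 0.0) * tree.feature_importances_
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class weighted vote tallies sum_m alpha_m 1[h_m(x) = c]."""
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree, a in zip(self.estimators_, self.estimator_weights_):
            pred = tree.predict(X)
            votes[np.arange(len(pred)), pred] += a
        return votes

    def predict(self, X):
        votes = self.decision_function(X)
        return self.classes_[np.argmax(votes, axis=1)]


# ---------------------------------------------------------------------------
# DataFrame-level operations (records = phenology table with an 'rp' label)


@dataclass
class CvReport:
    error_rate: float
    success_rate: float
    per_fold: list = field(default_factory=list)
    n_used: int = 0
    n_dropped_missing: int = 0

    @classmethod
    def from_error(cls, error_rate: float) -> "CvReport":
        """Report with the success rate as the exact complement of the error."""
        if not 0 <= error_rate <= 1:
            raise ValueError("error_rate must lie in [0, 1]")
        return cls(error_rate=error_rate, success_rate=1.0 - error_rate)

    @property
    def error_percent(self) -> float:
        return 100.0 * self.error_rate

    @property
    def success_percent(self) -> float:
        return 100.0 * self.success_rate


_NON_FEATURE_COLS = {"bird_id", "season_year", "sex", "rp"}


def _extract_xy(records: pd.DataFrame, features=None):
    if features is None:
        features = [f for f in FEATURE_REGISTRY if f in records.columns]
        if not features:  # free-form table: every non-metadata column
            features = [c for c in records.columns if c not in _NON_FEATURE_COLS]
    missing = [f for f in features if f not in records.columns]
    if missing:
        raise KeyError(f"unknown feature names: {missing}")
    sub = records[list(features) + ["rp"]]
    ok = sub[list(features)].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} records with missing features")
    sub = sub[ok]
    return sub[list(features)].to_numpy(float), sub["rp"].to_numpy(), list(features), n_dropped


def train_samme(
    records: pd.DataFrame,
    features=None,
    m_rounds: int = 100,
    tree_depth: int = 1,
    seed=None,
) -> SammeClassifier:
    """Fit a SAMME model to a phenology table (label column ``rp``)."""
    X, y, feats, _ = _extract_xy(records, features)
    model = SammeClassifier(
        n_estimators=m_rounds, max_depth=tree_depth, random_state=seed
    ).fit(X, y)
    model.feature_names_ = feats
    return model


def predict(model: SammeClassifier, records: pd.DataFrame) -> np.ndarray:
    feats = getattr(model, "feature_names_", None)
    if feats is None:
        raise ValueError("model was not trained through train_samme")
    missing = [f for f in feats if f not in records.columns]
    if missing:
        raise KeyError(f"records lack model features: {missing}")
    return model.predict(records[feats].to_numpy(float))


def cv_error(
    records: pd.DataFrame,
    features=None,
    k_folds: int = 10,
    m_rounds: int = 100,
    tree_depth: int = 1,
    seed=None,
) -> CvReport:
    """Stratified k-fold cross-validated misclassification of the booster.

    Pooled error over held-out folds; the success rate is its exact
    complement.  If the rarest class has fewer members than ``k_folds`` the
    fold count degrades to that class count (with a warning) so stratification
    stays valid.
    """
    X, y, _, n_dropped = _extract_xy(records, features)
    n = len(y)
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds n={n}")
    _, counts = np.unique(y, return_counts=True)
    k_eff = int(min(k_folds, counts.min()))
    if k_eff < 2:
        raise ValueError("rarest class too small for cross-validation")
    if k_eff < k_folds:
        warnings.warn(
            f"reducing folds from {k_folds} to {k_eff} (rarest class size)"
        )
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    n_err = 0
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = SammeClassifier(
            n_estimators=m_rounds, max_depth=tree_depth, random_state=seed
        ).fit(X[tr], y[tr])
        pred = model.predict(X[te])
        fold_err = int((pred != y[te]).sum())
        n_err += fold_err
        per_fold.append(
            {"fold": fold, "n": len(te), "errors": fold_err, "rate": fold_err / len(te)}
        )
    err = n_err / n
    return CvReport(
        error_rate=err,
        success_rate=1.0 - err,
        per_fold=per_fold,
        n_used=n,
        n_dropped_missing=n_dropped,
    )


def permutation_pvalue(
    records: pd.DataFrame,
    features=None,
    n_perm: int = 199,
    k_folds: int = 10,
    m_rounds: int = 100,
    tree_depth: int = 1,
    seed=None,
) -> float:
    """Label-permutation significance of the cross-validated error.

    Labels are permuted within sex strata (sex composition could otherwise
    masquerade as signal); the add-one estimate
    p = (1 + #{permuted error <= observed}) / (n_perm + 1) bounds the
    attainable p at 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = cv_error(
        records, features, k_folds, m_rounds, tree_depth, seed=seed
    ).error_rate
    groups = (
        records["sex"].to_numpy()
        if "sex" in records.columns
        else np.zeros(len(records), dtype=int)
    )
    count = 0
    for _ in range(int(n_perm)):
        perm = records.copy()
        rp = perm["rp"].to_numpy().copy()
        for g in np.unique(groups):
            idx = np.where(groups == g)[0]
            rp[idx] = rp[idx[rng.permutation(len(idx))]]
        perm["rp"] = rp
        e = cv_error(
            perm, features, k_folds, m_rounds, tree_depth,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).error_rate
        if e <= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def drop_correlated_features(
    records: pd.DataFrame, threshold: float = 0.9, features=None
) -> tuple[pd.DataFrame, list[str]]:
    """Greedily remove features until no |Pearson r| exceeds the threshold.

    At each step the worst-correlated pair is found and its member with the
    larger mean absolute correlation to everything else is dropped.  Constant
    features (undefined correlation) are flagged and excluded from testing.
    """
    X, _, feats, _ = _extract_xy(records, features)
    if len(feats) < 2:
        raise ValueError("need at least two features")
    sd = X.std(axis=0)
    constant = [f for f, s in zip(feats, sd) if s == 0]
    if constant:
        warnings.warn(f"constant features excluded from correlation test: {constant}")
    active = [f for f in feats if f not in constant]
    dropped: list[str] = []
    while len(active) >= 2:
        sub = records[active].to_numpy(float)
        sub = sub[~np.isnan(sub).any(axis=1)]
        corr = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_abs = corr.sum(axis=0) / (len(active) - 1)
        victim = i if mean_abs[i] >= mean_abs[j] else j
        dropped.append(active.pop(victim))
    keep_cols = [c for c in records.columns if c not in dropped]
    return records[keep_cols], dropped


def cumulative_importance_ranking(model: SammeClassifier) -> pd.DataFrame:
    """Features by descending importance with a cumulative column ending at 1."""
    check_is_fitted(model, "feature_importances_")
    names = getattr(
        model,
        "feature_names_",
        [f"x{i}" for i in range(len(model.feature_importances_))],
    )
    order = np.argsort(model.feature_importances_)[::-1]
    imp = model.feature_importances_[order]
    return pd.DataFrame(
        {
            "feature": [names[i] for i in order],
            "importance": imp,
            "cumulative_importance": np.cumsum(imp),
        }
    )
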