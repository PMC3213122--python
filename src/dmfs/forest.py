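"""Bagged-tree classifier with explicit out-of-bag bookkeeping.

A random forest in the classic parameterization: each tree is grown on a
bootstrap sample of the rows with a random subset of features considered
at each split (mtry = ceil(P/3) by default), and predictions are majority
votes over the ensemble.  The bagging loop is kept in this package so the
out-of-bag machinery the evaluation protocol needs — per-row OOB vote
fractions and per-tree OOB fractions — is an explicit, inspectable part
of the fitted state.  The trees themselves are scikit-learn decision
trees.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

DEFAULT_N_TREES = 500


def default_mtry(n_features: int) -> int:
    """Candidate split variables per node: one third of the predictors."""
    return max(1, math.ceil(n_features / 3))


class OOBForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with out-of-bag vote-fraction scores.

    Parameters
    ----------
    n_estimators : int, default 500
        Number of bootstrap-grown trees.
    max_features : int or None, default None
        Candidate split variables per node; None means ceil(P/3).
    random_state : int or None
        Seeds the bootstrap draws and the trees.

    Attributes
    ----------
    oob_score_fraction_ : ndarray of shape (n_samples,)
        Per-row fraction of out-of-bag trees voting for the positive
        class; NaN for rows that were never out of bag.
    per_tree_oob_fraction_ : ndarray of shape (n_estimators,)
        Fraction of rows left out of each tree's bootstrap sample
        (approaches 1 - 1/e for large samples).
    """

    def __init__(self, n_estimators: int = DEFAULT_N_TREES,
                 max_features: int | None = None,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        if np.asarray(X).ndim == 2 and np.asarray(X).shape[1] == 0:
            raise ValueError("feature matrix has zero columns")
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError(f"expected exactly 2 classes, got {self.classes_.size}")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if X.shape[1] == 0:
            raise ValueError("feature matrix has zero columns")
        n, p = X.shape
        mtry = self.max_features if self.max_features is not None else default_mtry(p)
        if not 1 <= mtry <= p:
            raise ValueError(f"max_features={mtry} outside [1, {p}]")
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        oob_votes = np.zeros(n)
        oob_counts = np.zeros(n)
        per_tree_oob = np.empty(self.n_estimators)
        for b in range(self.n_estimators):
            boot = rng.integers(0, n, size=n)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[boot] = True
            oob = ~in_bag
            per_tree_oob[b] = oob.mean()
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31)),
            )
            tree.fit(X[boot], y_enc[boot])
            self.estimators_.append(tree)
            if oob.any():
                votes = tree.predict(X[oob])
                oob_votes[oob] += votes
                oob_counts[oob] += 1
        self.per_tree_oob_fraction_ = per_tree_oob
        with np.errstate(invalid="ignore"):
            self.oob_score_fraction_ = np.where(oob_counts > 0,
                                                oob_votes / np.maximum(oob_counts, 1),
                                                np.nan)
        never_oob = int((oob_counts == 0).sum())
        if never_oob:
            warnings.warn(
                f"{never_oob} row(s) were never out-of-bag across "
                f"{self.n_estimators} trees; they carry no OOB score",
                stacklevel=2,
            )
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        votes = np.zeros(X.shape[0])
        for tree in self.estimators_:
            votes += tree.predict(X)
        pos = votes / len(self.estimators_)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]
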