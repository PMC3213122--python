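"""DMFSClassifier: the whole method as one sklearn estimator.

``fit(X, y)`` performs the internal stratified discovery/classification
split, discovers motifs on the discovery part only, scores the
classification part, and trains the final classifier on those features.
``predict``/``predict_proba``/``decision_function`` featurize new
sequences with the fitted motifs.  The discovery rows never touch the
final classifier — the anti-leakage contract at the heart of the method.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .classify_eval import RF, SVM, ClassifierSpec
from .featurize import MotifFeaturizer
from .forest import OOBForestClassifier
from .partition import SplitSpec, spawn_seed, stratified_split
from .seq_io import Dataset, LabeledSequence, get_alphabet


class DMFSClassifier(ClassifierMixin, BaseEstimator):
    """Discriminatory-motif feature selection + classification, end to end.

    Parameters mirror the pipeline's principal tuning knobs: the
    discovery fraction f, the motif length range and count, the
    mismatch allowance m, and the classifier (RF or SVM) with its
    parameters.

    Attributes
    ----------
    featurizer_ : fitted MotifFeaturizer (motifs found on discovery rows).
    model_ : fitted final classifier.
    discovery_index_, classification_index_ : row indices of the internal split.
    """

    def __init__(self, alphabet: str = "dna", discovery_fraction: float = 0.1,
                 classifier: str = RF, min_motif_len: int | None = None,
                 max_motif_len: int | None = None, n_motifs: int = 50,
                 mismatches: int | None = None, use_pwm: bool = False,
                 pvalue: float = 1e-3, n_trees: int = 500,
                 mtry: int | None = None, cost: float = 1.0,
                 gamma: float | None = None, random_state: int | None = None):
        self.alphabet = alphabet
        self.discovery_fraction = discovery_fraction
        self.classifier = classifier
        self.min_motif_len = min_motif_len
        self.max_motif_len = max_motif_len
        self.n_motifs = n_motifs
        self.mismatches = mismatches
        self.use_pwm = use_pwm
        self.pvalue = pvalue
        self.n_trees = n_trees
        self.mtry = mtry
        self.cost = cost
        self.gamma = gamma
        self.random_state = random_state

    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(kind=self.classifier, n_trees=self.n_trees,
                              mtry=self.mtry, cost=self.cost, gamma=self.gamma)

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("DMFSClassifier is a two-class method")
        alph = get_alphabet(self.alphabet)
        seqs = [LabeledSequence(f"row_{i:06d}", str(s).upper(), int(lab))
                for i, (s, lab) in enumerate(zip(X, y))]
        data = Dataset(seqs, alph)
        seed = 0 if self.random_state is None else int(self.random_state)
        split = stratified_split(data, SplitSpec(self.discovery_fraction,
                                                 spawn_seed(seed, 0)))
        disc_rows = sorted(int(s.split("_")[1]) for s in split.discovery_ids)
        clf_rows = sorted(int(s.split("_")[1]) for s in split.classification_ids)
        self.discovery_index_ = np.array(disc_rows)
        self.classification_index_ = np.array(clf_rows)

        featurizer = MotifFeaturizer(
            alphabet=self.alphabet, min_motif_len=self.min_motif_len,
            max_motif_len=self.max_motif_len, n_motifs=self.n_motifs,
            mismatches=self.mismatches, use_pwm=self.use_pwm, pvalue=self.pvalue,
        )
        X_arr = np.asarray(X, dtype=object)
        featurizer.fit(X_arr[self.discovery_index_], y[self.discovery_index_])
        self.featurizer_ = featurizer

        F = featurizer.transform(X_arr[self.classification_index_])
        y_clf = y[self.classification_index_]
        spec = self._spec()
        if spec.kind == RF:
            self.model_ = OOBForestClassifier(
                n_estimators=spec.n_trees,
                max_features=spec.resolved_mtry(F.shape[1]),
                random_state=spawn_seed(seed, 1),
            ).fit(F, y_clf)
            self.scaler_ = None
        else:
            self.scaler_ = StandardScaler().fit(F)
            self.model_ = SVC(C=spec.cost, kernel="rbf",
                              gamma=spec.resolved_gamma(F.shape[1]),
                              ).fit(self.scaler_.transform(F), y_clf)
        return self

    def _features(self, X) -> np.ndarray:
        check_is_fitted(self, "featurizer_")
        F = self.featurizer_.transform(np.asarray(X, dtype=object))
        return F if self.scaler_ is None else self.scaler_.transform(F)

    def predict(self, X):
        return self.model_.predict(self._features(X))

    def decision_function(self, X):
        F = self._features(X)
        if hasattr(self.model_, "decision_function"):
            return self.model_.decision_function(F)
        return self.model_.predict_proba(F)[:, 1]

    def predict_proba(self, X):
        F = self._features(X)
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(F)
        raise AttributeError("SVM variant exposes decision_function, not probabilities")
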