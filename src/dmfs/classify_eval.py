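"""Classifier training and evaluation: RF out-of-bag AUC, SVM cross-validated AUC.

The defaults mirror the standard parameterizations of the two
classifiers: random forests with 500 trees and mtry = ceil(P/3)
evaluated on out-of-bag observations, and an RBF support vector machine
with kernel width 1/P and soft-margin cost 1 evaluated by stratified
10-fold cross-validation (decision values pooled across folds into a
single AUC/ROC).  A grid-search tuner wraps either protocol.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .forest import DEFAULT_N_TREES, OOBForestClassifier, default_mtry
from .partition import stratified_folds
from .scoring import FeatureMatrix

RF = "rf"
SVM = "svm"


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to use and its tuning parameters.

    ``mtry`` (RF) and ``gamma`` (SVM kernel width) default to their
    feature-count-dependent values ceil(P/3) and 1/P when left None.
    """

    kind: str = RF
    n_trees: int = DEFAULT_N_TREES
    mtry: int | None = None
    cost: float = 1.0
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (RF, SVM):
            raise ValueError(f"classifier kind must be 'rf' or 'svm', got {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cost <= 0:
            raise ValueError("SVM cost must be > 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("SVM kernel width must be > 0")

    def resolved_mtry(self, n_features: int) -> int:
        return self.mtry if self.mtry is not None else default_mtry(n_features)

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_trees": self.n_trees, "mtry": self.mtry,
                "cost": self.cost, "gamma": self.gamma}


@dataclass
class RunResult:
    """AUC, ROC curve and provenance for a single evaluation."""

    auc: float
    roc: np.ndarray                    # columns: fpr, tpr, threshold
    spec: ClassifierSpec
    seed: int
    n_excluded: int = 0
    motif_words: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"auc": self.auc, "spec": self.spec.to_dict(), "seed": self.seed,
                   "n_excluded": self.n_excluded, "motifs": self.motif_words}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def roc_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\tthreshold\n")
            for fpr, tpr, thr in self.roc:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\t{thr:.10g}\n")


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability a random positive outscores a random
    negative, with ties contributing 1/2.  Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


def rf_oob_auc(fm: FeatureMatrix, spec: ClassifierSpec | None = None,
               seed: int = 0) -> RunResult:
    """Fit the forest and compute AUC on out-of-bag vote fractions.

    Rows never out of bag (vanishingly rare at 500 trees) are excluded
    from the AUC with a warning.
    """
    spec = spec or ClassifierSpec(kind=RF)
    if spec.kind != RF:
        raise ValueError("rf_oob_auc requires an RF spec")
    forest = OOBForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.resolved_mtry(fm.n_features),
        random_state=seed,
    )
    forest.fit(fm.values, fm.labels)
    scores = forest.oob_score_fraction_
    usable = ~np.isnan(scores)
    result = RunResult(
        auc=compute_auc(scores[usable], fm.labels[usable]),
        roc=_roc_points(scores[usable], fm.labels[usable]),
        spec=spec,
        seed=seed,
        n_excluded=int((~usable).sum()),
        motif_words=list(fm.columns),
    )
    return result


def svm_cv_auc(fm: FeatureMatrix, spec: ClassifierSpec | None = None,
               seed: int = 0, n_folds: int = 10) -> RunResult:
    """Stratified k-fold CV for the RBF-SVM; pooled decision-value AUC.

    Features are standardized with training-fold statistics only.  If a
    class has fewer rows than ``n_folds`` the fold count is reduced to
    the minimum class size, with a warning.
    """
    spec = spec or ClassifierSpec(kind=SVM)
    if spec.kind != SVM:
        raise ValueError("svm_cv_auc requires an SVM spec")
    labels = fm.labels
    min_class = min(int((labels == 1).sum()), int((labels == 0).sum()))
    if min_class < 2:
        raise ValueError("each class needs at least 2 rows for cross-validation")
    k = n_folds
    if min_class < n_folds:
        k = min_class
        warnings.warn(f"class with {min_class} rows < {n_folds} folds; using k={k}",
                      stacklevel=2)
    folds = stratified_folds(fm.ids, list(labels), k, seed)
    row_of = {sid: i for i, sid in enumerate(fm.ids)}
    gamma = spec.resolved_gamma(fm.n_features)
    pooled = np.empty(len(fm.ids))
    for fold_ids in folds:
        val_idx = np.array([row_of[s] for s in fold_ids])
        train_mask = np.ones(len(fm.ids), dtype=bool)
        train_mask[val_idx] = False
        scaler = StandardScaler().fit(fm.values[train_mask])
        clf = SVC(C=spec.cost, kernel="rbf", gamma=gamma)
        clf.fit(scaler.transform(fm.values[train_mask]), labels[train_mask])
        pooled[val_idx] = clf.decision_function(scaler.transform(fm.values[val_idx]))
    return RunResult(
        auc=compute_auc(pooled, labels),
        roc=_roc_points(pooled, labels),
        spec=spec,
        seed=seed,
        motif_words=list(fm.columns),
    )


def default_grid(spec: ClassifierSpec, n_features: int) -> dict[str, list]:
    """Modest grids symmetric around the default parameterization."""
    if spec.kind == RF:
        p = n_features
        return {"mtry": sorted({default_mtry(p), max(1, int(np.ceil(np.sqrt(p)))), p})}
    return {"cost": [0.1, 1.0, 10.0, 100.0],
            "gamma": [0.1 / n_features, 1.0 / n_features, 10.0 / n_features]}


def evaluate(fm: FeatureMatrix, spec: ClassifierSpec, seed: int) -> RunResult:
    """Dispatch to the spec's evaluation protocol (OOB for RF, CV for SVM)."""
    if spec.kind == RF:
        return rf_oob_auc(fm, spec, seed)
    return svm_cv_auc(fm, spec, seed)


def grid_tune(fm: FeatureMatrix, spec: ClassifierSpec,
              grid: Mapping[str, Sequence] | None = None,
              seed: int = 0) -> tuple[ClassifierSpec, RunResult]:
    """Evaluate every grid point and return the AUC-maximizing spec.

    Ties break toward the default spec first, then lexicographically on
    the parameter tuple.  The default point is always included.
    """
    grid = dict(grid) if grid else default_grid(spec, fm.n_features)
    if not grid:
        raise ValueError("tuning grid is empty")
    names = sorted(grid)
    candidates = [replace(spec, **dict(zip(names, combo)))
                  for combo in itertools.product(*(grid[n] for n in names))]
    if spec not in candidates:
        candidates.insert(0, spec)
    best: tuple[float, int, tuple, ClassifierSpec, RunResult] | None = None
    for cand in candidates:
        result = evaluate(fm, cand, seed)
        is_default = 0 if cand == spec else 1
        key_tuple = tuple(getattr(cand, n) if getattr(cand, n) is not None else -1
                          for n in names)
        key = (-result.auc, is_default, key_tuple)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (result.auc, is_default, key_tuple, cand, result)
    assert best is not None
    return best[3], best[4]
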