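"""Linear SVM group classification with LOOCV and SFFS subset search.

The classifier is a linear maximum-margin support vector machine;
accuracy is estimated by leave-one-out cross-validation (each subject
is predicted by a model that never saw it).  The subset search is
sequential floating forward selection (SFFS): greedy forward additions
maximizing the LOOCV accuracy criterion, each followed by conditional
backward removals accepted only while they strictly improve on the
best accuracy previously recorded for the smaller subset size.  The
criterion is evaluated by LOOCV over the full dataset (non-nested),
matching the analysis design whose selection optimism the
feature-selection control in :mod:`falffmvpa.permutation` quantifies.

The treatment group is the positive class throughout; sensitivity is
the true-positive rate on treated subjects, specificity the
true-negative rate on sham subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .synth import TREATMENT

__all__ = [
    "SubsetResult",
    "SFFSStep",
    "SFFSTrace",
    "encode_labels",
    "train_linear_margin_classifier",
    "loocv",
    "sffs",
    "exhaustive_search",
]


@dataclass(frozen=True)
class SubsetResult:
    """LOOCV outcome for one feature subset.

    ``ca`` is percent correct; sensitivity/specificity/balanced accuracy
    are proportions; ``dor`` is the diagnostic odds ratio
    (sens*spec) / ((1-sens)(1-spec)), with a Haldane 0.5 continuity
    correction applied to the 2x2 counts when any cell is zero.
    """

    subset: tuple[str, ...]
    ca: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    dor: float
    per_fold_predictions: tuple[int, ...]

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset), "ca": self.ca,
            "confusion": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy, "dor": self.dor,
        }


@dataclass(frozen=True)
class SFFSStep:
    action: str  # "add" | "remove"
    feature: str
    subset: tuple[str, ...]
    criterion: float  # LOOCV CA (%) of the resulting subset


@dataclass
class SFFSTrace:
    steps: list[SFFSStep] = field(default_factory=list)
    #: size -> (subset in inclusion order, CA %)
    best_per_size: dict[int, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "steps": [{"action": s.action, "feature": s.feature,
                       "subset": list(s.subset), "criterion": s.criterion}
                      for s in self.steps],
            "best_per_size": {str(k): {"subset": list(v[0]), "ca": v[1]}
                              for k, v in self.best_per_size.items()},
            "n_evaluations": self.n_evaluations,
        }


def encode_labels(y: Sequence) -> np.ndarray:
    """Map group labels to {0, 1} with the treatment group positive.

    Accepts 0/1 integers, booleans, or 'tVNS'/'sham' strings.
    """
    arr = np.asarray(y)
    if arr.dtype.kind in "OU":
        known = {TREATMENT: 1, "sham": 0, "treatment": 1, "control": 0}
        try:
            out = np.array([known[str(v)] for v in arr])
        except KeyError as e:
            raise ValueError(f"unrecognised group label {e.args[0]!r}") from None
    else:
        out = arr.astype(int)
        if not np.isin(out, (0, 1)).all():
            raise ValueError("numeric labels must be 0/1")
    return out


def _as_matrix(X, subset: Sequence[str] | None):
    """(matrix, column names) from a DataFrame or array."""
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c != "group"]
        if subset is not None:
            missing = [s for s in subset if s not in cols]
            if missing:
                raise KeyError(f"subset features not in table: {missing}")
            cols = list(subset)
        return X[cols].to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = [f"f{i}" for i in range(X.shape[1])]
    if subset is not None:
        idx = [cols.index(s) if isinstance(s, str) else int(s) for s in subset]
        return X[:, idx], [cols[i] for i in idx]
    return X, cols


def train_linear_margin_classifier(X, y, c_reg: float = 1.0) -> SVC:
    """Fit a linear maximum-margin classifier (C-SVM).

    Returns the fitted model; ``coef_`` and ``intercept_`` hold the
    separating hyperplane's weights and bias.
    """
    if c_reg <= 0:
        raise ValueError("c_reg must be positive")
    Xm, _ = _as_matrix(X, None)
    yv = encode_labels(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("training data contains a single class")
    if not np.all(np.isfinite(Xm)):
        raise ValueError("non-finite feature values")
    clf = SVC(kernel="linear", C=c_reg, class_weight="balanced")
    clf.fit(Xm, yv)
    return clf


def _confusion_metrics(y: np.ndarray, pred: np.ndarray) -> dict:
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ba = (sens + spec) / 2.0
    if min(tp, fn, tn, fp) == 0:
        # Haldane continuity correction keeps the odds ratio finite
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    else:
        dor = (sens * spec) / ((1.0 - sens) * (1.0 - spec))
    ca = 100.0 * (tp + tn) / len(y)
    return dict(tp=tp, fn=fn, tn=tn, fp=fp, sensitivity=sens, specificity=spec,
                balanced_accuracy=ba, dor=dor, ca=ca)


def _loocv_core(Xm: np.ndarray, yv: np.ndarray, names: tuple[str, ...],
                c_reg: float) -> SubsetResult:
    n = Xm.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if Xm.shape[1] < 1:
        raise ValueError("subset must be non-empty")
    if yv.min() == yv.max():
        raise ValueError("training data contains a single class")
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    # Per-fold balanced class weights: every LOOCV training set is one
    # subject short in the held-out class, which would otherwise tilt the
    # margin toward the majority class and pull the null accuracy below
    # the 50% chance level.  Inverse-frequency weighting restores the
    # balanced-prior problem in each fold, so the weights must be
    # recomputed per fold and no fold can be skipped.
    for i in range(n):
        tr = idx != i
        ytr = yv[tr]
        if ytr.min() == ytr.max():
            raise ValueError(f"fold {i}: training labels are single-class")
        clf = SVC(kernel="linear", C=c_reg, shrinking=False,
                  class_weight="balanced")
        clf.fit(Xm[tr], ytr)
        preds[i] = int(clf.predict(Xm[i:i + 1])[0])
    m = _confusion_metrics(yv, preds)
    return SubsetResult(subset=names, per_fold_predictions=tuple(preds), **m)


def loocv(X, y, subset: Sequence[str] | None = None, c_reg: float = 1.0) -> SubsetResult:
    """Leave-one-out cross-validation of the linear SVM on a subset.

    Each subject is predicted by a model trained on the other n-1;
    CA = 100 * (correct predictions) / n.
    """
    Xm, cols = _as_matrix(X, subset)
    yv = encode_labels(y)
    return _loocv_core(Xm, yv, tuple(cols), c_reg)


def sffs(
    X,
    y,
    max_size: int | None = None,
    c_reg: float = 1.0,
) -> tuple[SFFSTrace, SubsetResult]:
    """Sequential floating forward selection over the feature columns.

    Forward steps add the candidate maximizing LOOCV CA (ties broken by
    catalog order); after each addition, backward steps remove features
    while removal strictly improves on the best CA recorded at the
    smaller size.  The best result is the highest-CA subset, ties broken
    by smaller size, then by order of discovery.

    Returns the search trace and the best subset's LOOCV result.
    """
    Xm, cols = _as_matrix(X, None)
    yv = encode_labels(y)
    n_feat = len(cols)
    if n_feat < 1:
        raise ValueError("need at least one feature")
    if max_size is None:
        max_size = n_feat
    if max_size < 1 or max_size > n_feat:
        raise ValueError(f"max_size must be in [1, {n_feat}]")

    cache: dict[frozenset, SubsetResult] = {}
    trace = SFFSTrace()

    def evaluate(subset_order: tuple[str, ...]) -> SubsetResult:
        key = frozenset(subset_order)
        if key not in cache:
            trace.n_evaluations += 1
            ordered = tuple(sorted(subset_order, key=cols.index))
            sel = [cols.index(f) for f in ordered]
            cache[key] = _loocv_core(Xm[:, sel], yv, ordered, c_reg)
        return cache[key]

    current: tuple[str, ...] = ()

    def record(subset_order: tuple[str, ...], ca: float) -> None:
        k = len(subset_order)
        if k and (k not in trace.best_per_size or ca > trace.best_per_size[k][1]):
            trace.best_per_size[k] = (subset_order, ca)

    while len(current) < max_size:
        # forward: add the best remaining candidate
        best_feat, best_ca = None, -np.inf
        for f in cols:  # catalog order breaks ties
            if f in current:
                continue
            ca = evaluate(current + (f,)).ca
            if ca > best_ca:
                best_feat, best_ca = f, ca
        current = current + (best_feat,)
        trace.steps.append(SFFSStep("add", best_feat, current, best_ca))
        record(current, best_ca)

        # floating: conditional exclusions while strictly better than the
        # best subset previously seen at the smaller size
        while len(current) > 2:
            best_rm, best_rm_ca = None, -np.inf
            for f in current:
                ca = evaluate(tuple(g for g in current if g != f)).ca
                if ca > best_rm_ca:
                    best_rm, best_rm_ca = f, ca
            smaller = len(current) - 1
            prev_best = trace.best_per_size.get(smaller, (None, -np.inf))[1]
            if best_rm_ca > prev_best:
                current = tuple(g for g in current if g != best_rm)
                trace.steps.append(SFFSStep("remove", best_rm, current, best_rm_ca))
                record(current, best_rm_ca)
            else:
                break

    # smallest subset with the highest CA; earlier discovery wins remaining ties
    best_size = min(
        trace.best_per_size,
        key=lambda k: (-trace.best_per_size[k][1], k),
    )
    best_subset = trace.best_per_size[best_size][0]
    return trace, evaluate(best_subset)


def exhaustive_search(X, y, max_size: int | None = None,
                      c_reg: float = 1.0) -> SubsetResult:
    """Best subset by brute-force enumeration (oracle for small feature
    counts).  Ties broken by smaller size, then lexicographic catalog
    order — the same preference SFFS uses."""
    from itertools import combinations

    Xm, cols = _as_matrix(X, None)
    yv = encode_labels(y)
    if max_size is None:
        max_size = len(cols)
    best: SubsetResult | None = None
    for k in range(1, max_size + 1):
        for combo in combinations(cols, k):
            sel = [cols.index(c) for c in combo]
            res = _loocv_core(Xm[:, sel], yv, combo, c_reg)
            if best is None or res.ca > best.ca:
                best = res
    return best
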