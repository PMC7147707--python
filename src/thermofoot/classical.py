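"""Classical MLP / linear-SVM baselines with the OVO evaluation protocol.

Feature vectors are classified pairwise: each unordered pair of the five
thermal-change classes forms one binary task, ten tasks in all for five
classes.  Tasks are ordered by decreasing class distance, then by
descending upper class, which reproduces the customary report order
(1-5, 2-5, 1-4, 3-5, 2-4, 1-3, 4-5, 3-4, 2-3, 1-2).

The split protocol reserves 85% of each task for training, 5% for
validation and 10% for testing; 10-fold stratified cross-validation is
used for the tabulated reports.  At these task sizes the validation
portion is a few samples, so it is scored and reported rather than used
as a stopping monitor (a score-based stopper saturates immediately on so
few samples and would freeze the network near its initialization).
Features are z-scored on the training portion before fitting — required
for scale-sensitive margins and harmless for the MLP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import ConfusionCounts, MetricsRow, metrics_from_counts, pair_table, roc_auc
from .thermogram import ValidationError

__all__ = ["SplitProtocol", "PairTask", "FittedBaseline", "make_ovo_tasks",
           "fit_mlp", "fit_svm", "evaluate_ovo"]


@dataclass(frozen=True)
class SplitProtocol:
    train_frac: float = 0.85
    val_frac: float = 0.05
    test_frac: float = 0.10
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


@dataclass
class PairTask:
    """One binary one-vs-one task; ``class_b`` is the positive class."""

    class_a: int
    class_b: int
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise ValidationError("a pair needs two distinct classes")
        present = set(np.unique(self.y))
        if present != {self.class_a, self.class_b}:
            raise ValidationError(
                f"task ({self.class_a},{self.class_b}) has labels {sorted(present)}")

    @property
    def binary_y(self) -> np.ndarray:
        return (self.y == self.class_b).astype(int)


def make_ovo_tasks(X: np.ndarray, y: np.ndarray) -> List[PairTask]:
    """One task per unordered pair of classes present in ``y``.

    Pairs are ordered by decreasing class distance, ties by descending
    upper class.  Pairs involving an absent class are skipped with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValidationError("need at least two classes for OVO tasks")
    counts = {c: int((y == c).sum()) for c in classes}
    pairs = sorted(combinations(classes, 2), key=lambda ab: (-(ab[1] - ab[0]), -ab[1]))
    tasks = []
    for a, b in pairs:
        if counts[a] == 0 or counts[b] == 0:
            warnings.warn(f"pair ({a},{b}) skipped: empty class", stacklevel=2)
            continue
        sel = (y == a) | (y == b)
        tasks.append(PairTask(class_a=a, class_b=b, X=X[sel], y=y[sel]))
    return tasks


@dataclass
class FittedBaseline:
    model: Pipeline
    task: PairTask
    counts: ConfusionCounts
    metrics: MetricsRow
    test_scores: np.ndarray
    test_labels: np.ndarray
    #: accuracy on the held-out 5% validation portion (nan if empty)
    val_accuracy: float = float("nan")


def _make_model(kind: str, protocol: SplitProtocol, hidden_layers: Tuple[int, ...]) -> Pipeline:
    if kind == "mlp":
        # Tasks here have a handful of samples, so a score-based stopper on
        # the tiny validation portion saturates immediately and would
        # restore near-initial weights; the network therefore trains to
        # loss convergence and the held-out validation split is scored
        # separately (see _fit).
        clf = MLPClassifier(hidden_layer_sizes=hidden_layers, max_iter=3000,
                            learning_rate_init=0.01, early_stopping=False,
                            n_iter_no_change=50, random_state=protocol.seed)
    elif kind == "svm":
        clf = SVC(kernel="linear", random_state=protocol.seed)
    else:
        raise ValidationError(f"unknown model kind {kind!r}")
    return make_pipeline(StandardScaler(), clf)


def _decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    clf = model[-1]
    if hasattr(clf, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def _fit(kind: str, task: PairTask, protocol: SplitProtocol,
         hidden_layers: Tuple[int, ...]) -> FittedBaseline:
    y = task.binary_y
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValidationError("each class needs at least 2 samples for the split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        task.X, y, test_size=protocol.test_frac, stratify=y, random_state=protocol.seed)
    # carve the 5% validation portion out of the remaining 90%
    val_of_rest = protocol.val_frac / (protocol.train_frac + protocol.val_frac)
    X_va = y_va = None
    if val_of_rest > 0 and min(np.bincount(y_tr, minlength=2)) >= 2:
        n_val = max(1, int(round(val_of_rest * len(y_tr))))
        if len(y_tr) - n_val >= 2:
            X_tr, X_va, y_tr, y_va = train_test_split(
                X_tr, y_tr, test_size=n_val, stratify=None,
                random_state=protocol.seed + 1)
    model = _make_model(kind, protocol, hidden_layers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y_te == 1)).sum()),
        fp=int(((pred == 1) & (y_te == 0)).sum()),
        tn=int(((pred == 0) & (y_te == 0)).sum()),
        fn=int(((pred == 0) & (y_te == 1)).sum()),
    )
    scores = _decision_scores(model, X_te)
    auc = roc_auc(scores, y_te)[0] if len(np.unique(y_te)) == 2 else float("nan")
    val_acc = float(model.score(X_va, y_va)) if X_va is not None else float("nan")
    return FittedBaseline(model=model, task=task, counts=counts,
                          metrics=metrics_from_counts(counts, auc=auc),
                          test_scores=scores, test_labels=y_te,
                          val_accuracy=val_acc)


def fit_mlp(task: PairTask, protocol: SplitProtocol = SplitProtocol(),
            hidden_layers: Tuple[int, ...] = (10,)) -> FittedBaseline:
    """Feed-forward network (input-hidden-output) on the 85/5/10 split."""
    return _fit("mlp", task, protocol, hidden_layers)


def fit_svm(task: PairTask, protocol: SplitProtocol = SplitProtocol(),
            kernel: str = "linear") -> FittedBaseline:
    """Linear-kernel maximum-margin classifier on the 85/10 split."""
    if kernel != "linear":
        raise ValidationError("only the linear kernel is part of the protocol")
    return _fit("svm", task, protocol, hidden_layers=())


def evaluate_ovo(
    X: np.ndarray,
    y: np.ndarray,
    protocol: SplitProtocol = SplitProtocol(),
    kind: str = "svm",
    hidden_layers: Tuple[int, ...] = (10,),
):
    """Cross-validated OVO report: one metric row per pair plus Average.

    Each pair runs ``cv_folds``-fold stratified CV; confusion counts are
    accumulated over folds and scores pooled for the AUC, mirroring the
    tabulated one-vs-one report layout.
    """
    rows: Dict[Tuple[int, int], MetricsRow] = {}
    for task in make_ovo_tasks(X, y):
        yb = task.binary_y
        folds = min(protocol.cv_folds, int(np.bincount(yb).min()))
        if folds < 2:
            warnings.warn(f"pair ({task.class_a},{task.class_b}) skipped: too few samples",
                          stacklevel=2)
            continue
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=protocol.seed)
        tp = fp = tn = fn = 0
        all_scores, all_labels = [], []
        for tr, te in skf.split(task.X, yb):
            model = _make_model(kind, protocol, hidden_layers)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(task.X[tr], yb[tr])
            pred = model.predict(task.X[te])
            yt = yb[te]
            tp += int(((pred == 1) & (yt == 1)).sum())
            fp += int(((pred == 1) & (yt == 0)).sum())
            tn += int(((pred == 0) & (yt == 0)).sum())
            fn += int(((pred == 0) & (yt == 1)).sum())
            all_scores.append(_decision_scores(model, task.X[te]))
            all_labels.append(yt)
        scores = np.concatenate(all_scores)
        labels = np.concatenate(all_labels)
        auc = roc_auc(scores, labels)[0]
        rows[(task.class_a, task.class_b)] = metrics_from_counts(
            ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), auc=auc)
    return pair_table(rows)
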