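"""k-NN and kernel-SVM classifiers with a leave-one-subject-out harness.

Accuracy is (TP + TN) / N — the fraction of subjects predicted correctly
over all leave-one-out folds.  k-NN is implemented directly (Euclidean
metric, distance ties broken by lower training-row index); the SVM is
scikit-learn's C-SVC behind the module's spec surface, with ``linear``,
``rbf`` and ``sigmoid`` (MLP, tanh) kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "knn_predict",
    "svm_train",
    "svm_predict",
    "make_classifier",
    "loocv",
]

KERNELS = ("linear", "rbf", "sigmoid")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and with what hyperparameters.

    ``gamma="auto"`` means 1 / (n_features * feature variance), evaluated on
    the training data at fit time.  Defaults: 3-NN; SVM with C = 1,
    coef0 = 0.
    """

    family: str = "svm"
    k: int = 3
    kernel: str = "sigmoid"
    C: float = 1.0
    gamma: float | str = "auto"
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("knn", "svm"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.family == "knn" and self.k < 1:
            raise ValueError("k >= 1 required")
        if self.family == "svm":
            if self.kernel not in KERNELS:
                raise ValueError(f"unknown kernel {self.kernel!r}")
            if self.C <= 0:
                raise ValueError("C must be > 0")

    @property
    def name(self) -> str:
        return f"{self.k}-NN" if self.family == "knn" else f"svm-{self.kernel}"


@dataclass
class CVResult:
    """Leave-one-subject-out predictions and overall accuracy."""

    subject_ids: list[str]
    truth: list[str]
    predictions: list[str]
    accuracy: float
    per_fold_log: list[dict] = field(default_factory=list)

    @classmethod
    def from_predictions(
        cls, subject_ids, truth, predictions, per_fold_log=None
    ) -> "CVResult":
        correct = sum(p == t for p, t in zip(predictions, truth))
        return cls(
            subject_ids=list(subject_ids),
            truth=list(truth),
            predictions=list(predictions),
            accuracy=correct / len(truth),
            per_fold_log=per_fold_log or [],
        )


def knn_predict(
    train_x: np.ndarray,
    train_y: Sequence[str],
    query: np.ndarray,
    k: int = 3,
) -> str:
    """Majority label of the k Euclidean-nearest training rows.

    Distance ties break toward the lower training-row index (stable sort).
    A vote tie (possible only for even k or >2 classes) resolves to the
    label of the nearest neighbour.
    """
    train_x = np.asarray(train_x, dtype=float)
    if train_x.ndim != 2 or len(train_x) == 0:
        raise ValueError("non-empty 2-D training matrix required")
    if k > len(train_x):
        raise ValueError(f"k={k} exceeds {len(train_x)} training rows")
    d = np.linalg.norm(train_x - np.asarray(query, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")[:k]
    votes: dict[str, int] = {}
    for i in order:
        votes[train_y[i]] = votes.get(train_y[i], 0) + 1
    top = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == top]
    if len(winners) == 1:
        return winners[0]
    return train_y[order[0]]


def _resolve_gamma(spec: ClassifierSpec) -> float | str:
    # sklearn's "scale" == 1 / (n_features * X.var()) == our "auto"
    return "scale" if spec.gamma == "auto" else spec.gamma


def svm_train(train_x: np.ndarray, train_y: Sequence[str], spec: ClassifierSpec) -> SVC:
    """Fit a soft-margin SVM.  Requires both classes present."""
    if spec.family != "svm":
        raise ValueError("spec.family must be 'svm'")
    y = np.asarray(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    model = SVC(
        kernel=spec.kernel,
        C=spec.C,
        gamma=_resolve_gamma(spec),
        coef0=spec.coef0,
        tol=1e-6,
        max_iter=200_000,  # sigmoid kernel can be indefinite; bound the solver
    )
    model.fit(np.asarray(train_x, dtype=float), y)
    return model


def svm_predict(model: SVC, query: np.ndarray) -> str:
    query = np.atleast_2d(np.asarray(query, dtype=float))
    return str(model.predict(query)[0])


class _KnnClassifier:
    def __init__(self, k: int):
        self.k = k

    def fit(self, x, y):
        self._x = np.asarray(x, dtype=float)
        self._y = list(y)
        return self

    def predict_one(self, q) -> str:
        return knn_predict(self._x, self._y, q, self.k)


class _SvmClassifier:
    def __init__(self, spec: ClassifierSpec):
        self.spec = spec

    def fit(self, x, y):
        self._model = svm_train(x, y, self.spec)
        return self

    def predict_one(self, q) -> str:
        return svm_predict(self._model, q)


def make_classifier(spec: ClassifierSpec):
    """Uniform fit/predict_one wrapper for either family."""
    return _KnnClassifier(spec.k) if spec.family == "knn" else _SvmClassifier(spec)


def loocv_predict(
    x: np.ndarray, y: Sequence[str], spec: ClassifierSpec
) -> list[str | None]:
    """Leave-one-row-out predictions; ``None`` for a fold whose training
    set lost a class (recorded, skipped)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    preds: list[str | None] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train_y = [y[j] for j in range(n) if mask[j]]
        if len(set(train_y)) < 2 and spec.family == "svm":
            preds.append(None)
        else:
            clf = make_classifier(spec).fit(x[mask], train_y)
            preds.append(clf.predict_one(x[i]))
        mask[i] = True
    return preds


def loocv(
    fm,
    spec: ClassifierSpec,
    feature_idx: Sequence[int] | None = None,
    mode: str = "replicate_paper",
    selector=None,
) -> CVResult:
    """Leave-one-subject-out cross-validation of a feature matrix.

    ``replicate_paper``: normalization and feature selection were computed
    once on all subjects upstream; folds only retrain the classifier.  This
    leaks selection information into the test fold (optimistic bias) but
    mirrors the original evaluation.  ``strict``: ``selector`` — a callable
    ``(FeatureMatrix) -> ordered feature indices`` — is re-run on the N-1
    training subjects of each fold, and Z1 statistics are recomputed from
    the training rows.

    Requires at least 3 subjects per class.
    """
    y = list(fm.labels)
    x_full = fm.values
    for lab in set(y):
        if y.count(lab) < 3:
            raise ValueError(f"need >= 3 subjects per class, class {lab!r} has {y.count(lab)}")
    n = len(y)
    preds: list[str] = []
    log: list[dict] = []
    if mode == "replicate_paper":
        cols = list(feature_idx) if feature_idx is not None else list(range(x_full.shape[1]))
        raw_preds = loocv_predict(x_full[:, cols], y, spec)
        for i, p in enumerate(raw_preds):
            if p is None:
                log.append({"fold": i, "skipped": "single-class training set"})
            preds.append(p if p is not None else "")
    elif mode == "strict":
        if selector is None:
            raise ValueError("strict mode requires a selector callable")
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            train_fm = replace(
                fm,
                values=x_full[mask],
                subject_ids=[fm.subject_ids[j] for j in range(n) if mask[j]],
                labels=[y[j] for j in range(n) if mask[j]],
            )
            if fm.normalization == "Z1":
                mu = train_fm.values.mean(axis=0)
                sd = np.std(train_fm.values, ddof=1, axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                train_vals = (train_fm.values - mu) / sd
                test_row = (x_full[i] - mu) / sd
                train_fm = replace(train_fm, values=train_vals)
            else:
                test_row = x_full[i]
            cols = list(selector(train_fm))
            clf = make_classifier(spec).fit(train_fm.values[:, cols], train_fm.labels)
            preds.append(clf.predict_one(test_row[cols]))
            log.append({"fold": i, "selected": cols})
            mask[i] = True
    else:
        raise ValueError(f"unknown cv mode {mode!r}")
    kept = [(s, t, p) for s, t, p in zip(fm.subject_ids, y, preds) if p]
    result = CVResult.from_predictions(
        [s for s, _, _ in kept], [t for _, t, _ in kept], [p for _, _, p in kept], log
    )
    return result
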