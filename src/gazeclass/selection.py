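"""Feature ranking by two-sample t-statistic and sequential forward selection.

Both selectors operate on a :class:`~gazeclass.features.FeatureMatrix` whose
rows split into the two group labels.  The t-ranking is purely
distributional; SFS greedily grows a feature set maximizing
leave-one-subject-out accuracy of a given classifier, so it tends to pick
less redundant features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import ClassifierSpec, CVResult, loocv
from .features import FeatureMatrix
from .io import GROUP_LABELS

__all__ = ["SelectionResult", "two_sample_t", "t_rank_select", "sfs_select"]


@dataclass
class SelectionResult:
    """Ordered selected feature indices and the criterion value at each step.

    For ``t_statistic`` the criterion is |t|; for ``sfs`` it is the
    leave-one-out accuracy achieved after adding the feature.
    """

    selected: list[int]
    criterion_values: list[float]
    method: str
    n_requested: int
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate feature indices in selection")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_requested": self.n_requested,
            "selected": self.selected,
            "criterion_values": self.criterion_values,
            "feature_names": self.feature_names,
        }


def two_sample_t(x_a, x_b, *, welch: bool = False) -> tuple[float, float]:
    """Two-sample t (pooled variance unless ``welch``) and two-sided p.

    Sign follows mean(a) - mean(b).  Zero variance with equal means gives
    (0, 1); each group needs at least 2 values.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if len(x_a) < 2 or len(x_b) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(x_a) == 0 and np.var(x_b) == 0:
        if np.mean(x_a) == np.mean(x_b):
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means")
    res = stats.ttest_ind(x_a, x_b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance
        if np.mean(x_a) == np.mean(x_b):
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means")
    return t, p


def _split_groups(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(fm.labels)
    a = fm.values[labels == GROUP_LABELS[0]]
    b = fm.values[labels == GROUP_LABELS[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be present")
    return a, b


def t_rank_select(fm: FeatureMatrix, n: int, *, welch: bool = False) -> SelectionResult:
    """Top-``n`` features by |t| between the two groups (ties: lower index)."""
    if n <= 0:
        raise ValueError("n must be positive")
    a, b = _split_groups(fm)
    tvals = np.array(
        [abs(two_sample_t(a[:, j], b[:, j], welch=welch)[0]) for j in range(fm.values.shape[1])]
    )
    # stable sort on -|t| keeps ties in increasing index order
    order = np.argsort(-tvals, kind="stable")[: min(n, len(tvals))]
    return SelectionResult(
        selected=[int(j) for j in order],
        criterion_values=[float(tvals[j]) for j in order],
        method="t_statistic",
        n_requested=n,
        feature_names=[fm.feature_names[j] for j in order],
    )


def sfs_select(
    fm: FeatureMatrix,
    n: int,
    spec: ClassifierSpec | None = None,
    *,
    evaluate=None,
) -> SelectionResult:
    """Sequential forward selection on leave-one-subject-out accuracy.

    Starting from the empty set, each step adds the feature whose addition
    maximizes the criterion (ties: lower feature index) until ``n`` features
    are selected.  ``evaluate(fm, cols) -> accuracy`` may override the
    default leave-one-out evaluator; the procedure is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = ClassifierSpec()
    if evaluate is None:
        def evaluate(fmx: FeatureMatrix, cols: list[int]) -> float:
            res: CVResult = loocv(fmx, spec, feature_idx=cols)
            return res.accuracy

    n_feat = fm.values.shape[1]
    selected: list[int] = []
    trajectory: list[float] = []
    while len(selected) < min(n, n_feat):
        best_j, best_acc = None, -np.inf
        for j in range(n_feat):
            if j in selected:
                continue
            try:
                acc = evaluate(fm, selected + [j])
            except Exception as exc:
                raise RuntimeError(
                    f"classifier failed evaluating candidate feature {j} "
                    f"({fm.feature_names[j]})"
                ) from exc
            if acc > best_acc:
                best_j, best_acc = j, acc
        selected.append(best_j)
        trajectory.append(float(best_acc))
    return SelectionResult(
        selected=selected,
        criterion_values=trajectory,
        method="sfs",
        n_requested=n,
        feature_names=[fm.feature_names[j] for j in selected],
    )
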