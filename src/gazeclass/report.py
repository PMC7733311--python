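"""Group-difference statistics per cluster and accuracy-grid aggregation.

All aggregation is exact arithmetic on full-precision values; rounding to
two decimals happens only when rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .io import GROUP_LABELS
from .selection import two_sample_t

__all__ = [
    "ClusterStat",
    "ImageGroupStats",
    "AccuracyGrid",
    "group_cluster_stats",
    "summarize_t_sums",
    "build_accuracy_grid",
    "aggregate_grids",
]


@dataclass
class ClusterStat:
    cluster: int
    feature_type: str  # "count" or "duration"
    mean_expert: float
    mean_layman: float
    t: float
    p: float


@dataclass
class ImageGroupStats:
    """Per-cluster group statistics for one image plus its summary row.

    ``sum_abs_t_*`` is the sum of |t| over clusters per feature type;
    ``best_p_*`` is the minimum p over clusters ("best cluster").
    """

    image_id: str
    sum_abs_t_count: float
    sum_abs_t_duration: float
    best_p_count: float
    best_p_duration: float
    optimal_k: float | None = None
    clusters: list[ClusterStat] = field(default_factory=list)
    n_tests: int = 0  # no multiple-testing correction applied; footnoted

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.clusters])


def group_cluster_stats(
    fm: FeatureMatrix, optimal_k: float | None = None
) -> ImageGroupStats:
    """Per-cluster group means, pooled t and two-sided p on raw (Z0) features."""
    if fm.normalization != "Z0":
        raise ValueError("group statistics are defined on unnormalized (Z0) features")
    labels = np.asarray(fm.labels)
    a = fm.values[labels == GROUP_LABELS[0]]  # experts
    b = fm.values[labels == GROUP_LABELS[1]]  # laymen
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be present")
    clusters: list[ClusterStat] = []
    for ftype, sl in (("count", fm.count_slice), ("duration", fm.duration_slice)):
        for j_local, j in enumerate(range(sl.start, sl.stop)):
            t, p = two_sample_t(a[:, j], b[:, j])
            clusters.append(
                ClusterStat(
                    cluster=j_local,
                    feature_type=ftype,
                    mean_expert=float(np.mean(a[:, j])),
                    mean_layman=float(np.mean(b[:, j])),
                    t=t,
                    p=p,
                )
            )
    counts = [c for c in clusters if c.feature_type == "count"]
    durs = [c for c in clusters if c.feature_type == "duration"]
    return ImageGroupStats(
        image_id=fm.image_id,
        sum_abs_t_count=float(sum(abs(c.t) for c in counts)),
        sum_abs_t_duration=float(sum(abs(c.t) for c in durs)),
        best_p_count=float(min(c.p for c in counts)),
        best_p_duration=float(min(c.p for c in durs)),
        optimal_k=optimal_k,
        clusters=clusters,
        n_tests=len(clusters),
    )


def summarize_t_sums(stats: list[ImageGroupStats]) -> dict:
    """Across-image means of t-sums, best-cluster p-values and optimal K.

    Permutation-invariant in the input list.
    """
    if not stats:
        raise ValueError("at least one image required")
    ks = [s.optimal_k for s in stats if s.optimal_k is not None]
    return {
        "per_image": {
            s.image_id: {
                "sum_abs_t_count": s.sum_abs_t_count,
                "sum_abs_t_duration": s.sum_abs_t_duration,
                "best_p_count": s.best_p_count,
                "best_p_duration": s.best_p_duration,
                "optimal_k": s.optimal_k,
            }
            for s in stats
        },
        "mean_sum_abs_t_count": float(np.mean([s.sum_abs_t_count for s in stats])),
        "mean_sum_abs_t_duration": float(
            np.mean([s.sum_abs_t_duration for s in stats])
        ),
        "mean_best_p_count": float(np.mean([s.best_p_count for s in stats])),
        "mean_best_p_duration": float(np.mean([s.best_p_duration for s in stats])),
        "mean_optimal_k": float(np.mean(ks)) if ks else None,
    }


@dataclass
class AccuracyGrid:
    """Pictures x normalization accuracy table with exact means."""

    pictures: list[str]
    normalizations: list[str]
    values: np.ndarray  # len(pictures) x len(normalizations)
    title: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pictures), len(self.normalizations)):
            raise ValueError("grid shape mismatch")

    @property
    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        """Mean over all cells."""
        return float(self.values.mean())

    def row_mean(self, picture: str) -> float:
        return float(self.row_means[self.pictures.index(picture)])

    def to_dataframe(self, decimals: int | None = None) -> pd.DataFrame:
        vals = self.values if decimals is None else np.round(self.values, decimals)
        df = pd.DataFrame(vals, index=self.pictures, columns=self.normalizations)
        df["mean"] = (
            self.row_means if decimals is None else np.round(self.row_means, decimals)
        )
        return df

    def to_markdown(self, decimals: int = 2) -> str:
        return self.to_dataframe(decimals).to_markdown()


def build_accuracy_grid(
    results: dict[tuple[str, str], float], title: str = ""
) -> AccuracyGrid:
    """Assemble a complete (picture, normalization) -> accuracy map into a grid.

    Values may be floats or objects with an ``accuracy`` attribute.  Missing
    cells raise, listing the absent keys.
    """
    pictures: list[str] = []
    norms: list[str] = []
    for pic, norm in results:
        if pic not in pictures:
            pictures.append(pic)
        if norm not in norms:
            norms.append(norm)
    missing = [
        (p, z) for p in pictures for z in norms if (p, z) not in results
    ]
    if missing:
        raise ValueError(f"incomplete accuracy grid; missing cells: {missing}")
    vals = np.empty((len(pictures), len(norms)))
    for i, p in enumerate(pictures):
        for j, z in enumerate(norms):
            cell = results[(p, z)]
            vals[i, j] = getattr(cell, "accuracy", cell)
    return AccuracyGrid(pictures, norms, vals, title=title)


def aggregate_grids(grids: list[AccuracyGrid]) -> dict[str, float]:
    """Per-normalization mean over all cells of all grids.

    Grids must share their normalization columns; permutation-invariant.
    """
    if not grids:
        raise ValueError("at least one grid required")
    norms = grids[0].normalizations
    for g in grids[1:]:
        if g.normalizations != norms:
            raise ValueError(
                f"normalization columns differ: {g.normalizations} vs {norms}"
            )
    stacked = np.vstack([g.values for g in grids])
    return {z: float(stacked[:, j].mean()) for j, z in enumerate(norms)}
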