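"""Published reference results used as worked-example inputs.

These are the accuracy tables and per-image cluster statistics reported by
the original expert/layman eye-tracking study whose analysis this package
implements.  The underlying recordings were never released, so these
printed values serve as inputs for exercising and checking the aggregation
operations, not as outputs of this code.
"""

from __future__ import annotations

from .report import AccuracyGrid, ImageGroupStats

__all__ = [
    "reference_accuracy_grids",
    "reference_image_summaries",
    "REFERENCE_CLUSTER_MEANS_P2",
    "PICTURES",
    "NORMALIZATION_COLUMNS",
]

PICTURES = ["P1", "P2", "P3", "P4", "P5"]
NORMALIZATION_COLUMNS = ["Z0", "Z1", "Z2", "Z3"]

# (title, 5x4 cells in picture-major order)
_GRIDS: list[tuple[str, list[list[float]]]] = [
    (
        "SVM-MLP, 10 best features, t-statistic",
        [
            [0.75, 0.89, 0.64, 0.67],
            [0.51, 0.77, 0.67, 0.62],
            [0.57, 0.54, 0.74, 0.71],
            [0.65, 0.54, 0.84, 0.62],
            [0.73, 0.73, 0.78, 0.63],
        ],
    ),
    (
        "3-NN, 10 best features, t-statistic",
        [
            [0.75, 0.75, 0.78, 0.81],
            [0.54, 0.56, 0.59, 0.59],
            [0.34, 0.60, 0.60, 0.60],
            [0.68, 0.65, 0.62, 0.65],
            [0.65, 0.55, 0.58, 0.55],
        ],
    ),
    (
        "SVM-linear, 10 best features, t-statistic",
        [
            [0.72, 0.75, 0.75, 0.81],
            [0.69, 0.77, 0.64, 0.56],
            [0.69, 0.69, 0.57, 0.60],
            [0.78, 0.65, 0.68, 0.70],
            [0.70, 0.70, 0.73, 0.68],
        ],
    ),
    (
        "SVM-RBF, 10 best features, t-statistic",
        [
            [0.58, 0.53, 0.64, 0.67],
            [0.62, 0.64, 0.44, 0.49],
            [0.57, 0.66, 0.54, 0.51],
            [0.62, 0.65, 0.59, 0.62],
            [0.60, 0.50, 0.55, 0.60],
        ],
    ),
    (
        "SVM-MLP, 5 best features, t-statistic",
        [
            [0.67, 0.86, 0.64, 0.89],
            [0.51, 0.46, 0.51, 0.77],
            [0.63, 0.63, 0.69, 0.51],
            [0.57, 0.57, 0.70, 0.81],
            [0.75, 0.55, 0.60, 0.65],
        ],
    ),
    (
        "SVM-MLP, 3 best features, SFS",
        [
            [0.72, 0.78, 0.83, 0.89],
            [0.72, 0.74, 0.59, 0.69],
            [0.83, 0.77, 0.71, 0.57],
            [0.70, 0.76, 0.76, 0.62],
            [0.83, 0.65, 0.70, 0.80],
        ],
    ),
    (
        "SVM-MLP, 5 best features, SFS",
        [
            [0.75, 0.89, 0.92, 0.81],
            [0.72, 0.51, 0.79, 0.72],
            [0.69, 0.80, 0.60, 0.69],
            [0.62, 0.65, 0.76, 0.81],
            [0.73, 0.78, 0.73, 0.78],
        ],
    ),
]

# per-image summary rows: t-sums per feature type, best-cluster p per
# feature type, and BIC-optimal cluster count
_IMAGE_SUMMARIES = {
    "P1": dict(t_count=8.26, t_duration=16.35, p_count=0.114, p_duration=0.001, k=11),
    "P2": dict(t_count=8.54, t_duration=13.65, p_count=0.071, p_duration=0.038, k=14),
    "P3": dict(t_count=9.81, t_duration=13.08, p_count=0.853, p_duration=0.041, k=12),
    "P4": dict(t_count=7.00, t_duration=10.96, p_count=0.229, p_duration=0.022, k=12),
    "P5": dict(t_count=4.98, t_duration=11.54, p_count=0.047, p_duration=0.055, k=12),
}

#: per-cluster group means for image P2, 14 clusters:
#: (expert count, layman count, expert mean duration ms, layman mean duration ms)
REFERENCE_CLUSTER_MEANS_P2 = [
    (13.60, 18.30, 214.3, 191.7),
    (10.90, 9.40, 192.1, 167.9),
    (4.90, 6.58, 178.8, 185.1),
    (4.60, 5.26, 218.8, 171.2),
    (3.90, 4.47, 117.0, 158.7),
    (3.50, 3.89, 164.4, 184.2),
    (3.30, 3.58, 166.8, 117.1),
    (3.15, 2.47, 126.4, 101.1),
    (2.55, 2.32, 143.8, 108.3),
    (1.45, 1.95, 119.3, 128.1),
    (1.35, 1.79, 128.0, 128.1),
    (0.85, 0.74, 44.9, 50.6),
    (0.70, 0.68, 60.7, 54.5),
    (0.65, 0.37, 44.0, 18.7),
]


def reference_accuracy_grids() -> list[AccuracyGrid]:
    """The seven published 5x4 accuracy tables as :class:`AccuracyGrid`."""
    return [
        AccuracyGrid(
            pictures=list(PICTURES),
            normalizations=list(NORMALIZATION_COLUMNS),
            values=cells,
            title=title,
        )
        for title, cells in _GRIDS
    ]


def reference_image_summaries() -> list[ImageGroupStats]:
    """Published per-image summary statistics as :class:`ImageGroupStats`."""
    return [
        ImageGroupStats(
            image_id=pic,
            sum_abs_t_count=row["t_count"],
            sum_abs_t_duration=row["t_duration"],
            best_p_count=row["p_count"],
            best_p_duration=row["p_duration"],
            optimal_k=row["k"],
        )
        for pic, row in _IMAGE_SUMMARIES.items()
    ]
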