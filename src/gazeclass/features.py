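"""Per-subject, per-cluster fixation features and Z0-Z3 normalizations.

For a K-cluster model of one image, each subject contributes 2K features:
``l_1..l_K`` (fixation counts per cluster) followed by ``t_1..t_K`` (mean
fixation duration per cluster, ms; 0 for an empty cluster).

Normalizations (z = (x - m) / sigma, sample standard deviation):

* ``Z0`` — raw features, no normalization.
* ``Z1`` — per feature column, over all subjects of the image.
* ``Z2`` — per subject, pooled over that subject's clusters across *all*
  images; count and duration features are pooled separately.
* ``Z3`` — per subject within a single image, again per feature type.

Degenerate groups (sigma = 0) map to z = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FixationDataset, filter_image
from .mixture import ClusterAssignment

__all__ = ["FeatureMatrix", "AlignmentError", "extract_features", "normalize",
           "NORMALIZATIONS"]

NORMALIZATIONS = ("Z0", "Z1", "Z2", "Z3")


class AlignmentError(ValueError):
    """Assignment and dataset lengths disagree."""


@dataclass
class FeatureMatrix:
    """Subjects x 2K feature matrix for one image."""

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    labels: list[str]
    image_id: str
    n_clusters: int
    normalization: str = "Z0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), 2 * self.n_clusters):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.subject_ids)}, {2 * self.n_clusters})"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def count_slice(self) -> slice:
        return slice(0, self.n_clusters)

    @property
    def duration_slice(self) -> slice:
        return slice(self.n_clusters, 2 * self.n_clusters)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.labels)
        return df

    def write(self, csv_path: str | Path) -> None:
        """CSV plus a JSON sidecar (image id, K, normalization)."""
        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "image_id": self.image_id,
                    "n_clusters": self.n_clusters,
                    "normalization": self.normalization,
                }
            )
        )

    @classmethod
    def read(cls, csv_path: str | Path) -> "FeatureMatrix":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        names = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            values=df[names].to_numpy(float),
            feature_names=names,
            subject_ids=df["subject_id"].astype(str).tolist(),
            labels=df["group"].tolist(),
            image_id=meta["image_id"],
            n_clusters=meta["n_clusters"],
            normalization=meta["normalization"],
        )


def feature_names(k: int) -> list[str]:
    return [f"l_{j + 1}" for j in range(k)] + [f"t_{j + 1}" for j in range(k)]


def extract_features(
    ds: FixationDataset,
    assignment: ClusterAssignment | np.ndarray,
    k: int,
    image_id: str,
) -> FeatureMatrix:
    """Count and mean-duration features per subject for one image.

    ``assignment`` must cover exactly the records of ``image_id`` (in the
    dataset's record order); a length mismatch raises
    :class:`AlignmentError`.  Subjects with no fixation on the image get no
    row.  Empty clusters contribute l = 0, t = 0.
    """
    labels = (
        assignment.labels if isinstance(assignment, ClusterAssignment) else
        np.asarray(assignment, dtype=int)
    )
    sub = filter_image(ds, image_id) if any(
        r.image_id != image_id for r in ds.records
    ) else ds
    if len(sub) != len(labels):
        raise AlignmentError(
            f"{len(labels)} cluster labels for {len(sub)} fixations on {image_id!r}"
        )
    subjects = sub.subjects  # first-appearance order
    counts = {s: np.zeros(k) for s in subjects}
    dursum = {s: np.zeros(k) for s in subjects}
    for rec, lab in zip(sub.records, labels):
        if not 0 <= lab < k:
            raise ValueError(f"cluster label {lab} outside 0..{k - 1}")
        counts[rec.subject_id][lab] += 1
        dursum[rec.subject_id][lab] += rec.duration
    rows = []
    for s in subjects:
        c = counts[s]
        with np.errstate(invalid="ignore"):
            t = np.where(c > 0, dursum[s] / np.maximum(c, 1), 0.0)
        rows.append(np.concatenate([c, t]))
    return FeatureMatrix(
        values=np.stack(rows),
        feature_names=feature_names(k),
        subject_ids=subjects,
        labels=[sub.group_of(s) for s in subjects],
        image_id=image_id,
        n_clusters=k,
        normalization="Z0",
    )


def _zscore(x: np.ndarray, m: float, s: float) -> np.ndarray:
    if s == 0 or not np.isfinite(s):
        return np.zeros_like(x)
    return (x - m) / s


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def normalize(
    fm: FeatureMatrix,
    method: str,
    all_images: list[FeatureMatrix] | None = None,
) -> FeatureMatrix:
    """Apply a Z0-Z3 normalization to a raw (Z0) feature matrix.

    ``Z2`` needs ``all_images`` — the subject's raw matrices across every
    image (including this one) — to pool the per-subject statistics.
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}")
    if method == "Z0":
        return replace(fm, values=fm.values.copy(), normalization="Z0")
    out = np.empty_like(fm.values)
    if method == "Z1":
        for j in range(fm.values.shape[1]):
            col = fm.values[:, j]
            out[:, j] = _zscore(col, float(np.mean(col)), _sd(col))
    elif method in ("Z2", "Z3"):
        if method == "Z2" and all_images is None:
            raise ValueError("Z2 requires all_images (per-subject pooling context)")
        pool_mats = all_images if method == "Z2" else [fm]
        for i, subj in enumerate(fm.subject_ids):
            for sl in (fm.count_slice, fm.duration_slice):
                pooled = []
                for other in pool_mats:
                    if subj in other.subject_ids:
                        row = other.subject_ids.index(subj)
                        osl = (
                            other.count_slice
                            if sl == fm.count_slice
                            else other.duration_slice
                        )
                        pooled.append(other.values[row, osl])
                vals = np.concatenate(pooled)
                out[i, sl] = _zscore(fm.values[i, sl], float(np.mean(vals)), _sd(vals))
    return replace(fm, values=out, normalization=method)
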