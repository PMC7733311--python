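"""Synthetic fixation cohorts with known ground truth.

Generates two-group (expert/layman) cohorts: per subject, image and
cluster, a Poisson number of fixations is drawn, positions come from the
cluster's bivariate Gaussian, and durations from a lognormal (default) or
truncated normal matched to the cluster/group mean and SD.  Group effects
live in the per-cluster count rates and duration means, mirroring the scale
of the published per-cluster group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

from .datasets import REFERENCE_CLUSTER_MEANS_P2
from .io import SCREEN_HEIGHT, SCREEN_WIDTH, FixationDataset, FixationRecord

__all__ = [
    "ImageSpec",
    "SyntheticSpec",
    "default_spec",
    "generate_cohort",
    "null_spec",
    "amplify_effects",
]

GROUP_ORDER = ("expert", "layman")  # column order of the (K, 2) rate matrices


@dataclass
class ImageSpec:
    """Ground-truth cluster layout and per-(cluster, group) emission rates."""

    image_id: str
    means: np.ndarray  # (K, 2) px
    covs: np.ndarray  # (K, 2, 2) px^2
    count_rate: np.ndarray  # (K, 2) Poisson means, columns (expert, layman)
    duration_mean: np.ndarray  # (K, 2) ms
    duration_sd: np.ndarray  # (K, 2) ms
    duration_family: str = "lognormal"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        self.count_rate = np.asarray(self.count_rate, dtype=float)
        self.duration_mean = np.asarray(self.duration_mean, dtype=float)
        self.duration_sd = np.asarray(self.duration_sd, dtype=float)

    @property
    def k_true(self) -> int:
        return len(self.means)

    def validate(self) -> None:
        k = self.k_true
        for name, arr, shape in [
            ("means", self.means, (k, 2)),
            ("covs", self.covs, (k, 2, 2)),
            ("count_rate", self.count_rate, (k, 2)),
            ("duration_mean", self.duration_mean, (k, 2)),
            ("duration_sd", self.duration_sd, (k, 2)),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.count_rate < 0):
            raise ValueError("count rates must be >= 0")
        if np.any(self.duration_mean <= 0) or np.any(self.duration_sd <= 0):
            raise ValueError("duration mean/sd must be > 0")
        if np.any(self.means[:, 0] < 0) or np.any(self.means[:, 0] > SCREEN_WIDTH):
            raise ValueError("cluster means outside the horizontal frame")
        if np.any(self.means[:, 1] < 0) or np.any(self.means[:, 1] > SCREEN_HEIGHT):
            raise ValueError("cluster means outside the vertical frame")
        for c in self.covs:
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("cluster covariances must be positive definite")
        if self.duration_family not in ("lognormal", "truncated-normal"):
            raise ValueError(f"unknown duration family {self.duration_family!r}")


@dataclass
class SyntheticSpec:
    n_experts: int = 23
    n_laymen: int = 21
    images: list[ImageSpec] = field(default_factory=list)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_experts < 1 or self.n_laymen < 1:
            raise ValueError("need at least one subject per group")
        if not self.images:
            raise ValueError("at least one image spec required")
        for img in self.images:
            img.validate()

    def to_yaml(self, path) -> None:
        doc = {
            "n_experts": self.n_experts,
            "n_laymen": self.n_laymen,
            "seed": self.seed,
            "images": [
                {
                    "image_id": im.image_id,
                    "means": im.means.tolist(),
                    "covs": im.covs.tolist(),
                    "count_rate": im.count_rate.tolist(),
                    "duration_mean": im.duration_mean.tolist(),
                    "duration_sd": im.duration_sd.tolist(),
                    "duration_family": im.duration_family,
                }
                for im in self.images
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        images = [ImageSpec(**im) for im in doc.pop("images")]
        return cls(images=images, **doc)


def _grid_layout(
    k: int, rng: np.random.Generator, sd_range=(22.0, 38.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Jittered grid of cluster centers with anisotropic covariances."""
    n_cols = int(np.ceil(np.sqrt(k * SCREEN_WIDTH / SCREEN_HEIGHT)))
    n_rows = int(np.ceil(k / n_cols))
    xs = (np.arange(n_cols) + 0.5) * SCREEN_WIDTH / n_cols
    ys = (np.arange(n_rows) + 0.5) * SCREEN_HEIGHT / n_rows
    centers = np.array([(x, y) for y in ys for x in xs])[:k]
    centers = centers + rng.uniform(-25, 25, size=centers.shape)
    centers[:, 0] = np.clip(centers[:, 0], 0, SCREEN_WIDTH)
    centers[:, 1] = np.clip(centers[:, 1], 0, SCREEN_HEIGHT)
    covs = []
    for _ in range(k):
        s1, s2 = rng.uniform(*sd_range, size=2)
        theta = rng.uniform(0, np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        covs.append(rot @ np.diag([s1**2, s2**2]) @ rot.T)
    return centers, np.stack(covs)


def default_spec(image_ids: list[str] | None = None, seed: int = 0) -> SyntheticSpec:
    """Cohort spec on the scale of the published study.

    23 experts vs. 21 laymen and a 14-cluster image per entry of
    ``image_ids`` (default one image, "P2").  Cluster 1 carries a group
    effect in the fixation count rate (13.6 vs. 18.3) and cluster 10 in the
    mean duration (119.3 vs. 128.1 ms); all other clusters use the pooled
    published magnitudes for both groups.  Duration SD defaults to 40% of
    the mean.  ``seed`` only fixes the cluster layout jitter.
    """
    if image_ids is None:
        image_ids = ["P2"]
    ref = np.array(REFERENCE_CLUSTER_MEANS_P2)  # (14, 4)
    k = len(ref)
    pooled_count = ref[:, :2].mean(axis=1)
    pooled_dur = ref[:, 2:].mean(axis=1)
    count_rate = np.column_stack([pooled_count, pooled_count])
    count_rate[0] = ref[0, :2]  # cluster 1 group effect
    duration_mean = np.column_stack([pooled_dur, pooled_dur])
    duration_mean[9] = ref[9, 2:]  # cluster 10 group effect
    duration_sd = 0.4 * duration_mean
    rng = np.random.default_rng(seed)
    images = []
    for image_id in image_ids:
        means, covs = _grid_layout(k, rng)
        images.append(
            ImageSpec(
                image_id=image_id,
                means=means,
                covs=covs,
                count_rate=count_rate.copy(),
                duration_mean=duration_mean.copy(),
                duration_sd=duration_sd.copy(),
            )
        )
    return SyntheticSpec(n_experts=23, n_laymen=21, images=images, seed=seed)


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Remove every group effect: rates and duration moments are averaged
    across groups.  Idempotent."""
    return amplify_effects(spec, 0.0)


def amplify_effects(spec: SyntheticSpec, factor: float) -> SyntheticSpec:
    """Scale each (cluster, group) deviation from the group-pooled value.

    ``factor`` 0 yields a null cohort, 1 leaves the spec unchanged, > 1
    amplifies group differences.  Rates are clipped at 0, duration means
    floored at 1 ms.
    """
    images = []
    for im in spec.images:
        def scaled(arr, floor):
            pooled = arr.mean(axis=1, keepdims=True)
            return np.maximum(pooled + factor * (arr - pooled), floor)

        images.append(
            replace(
                im,
                count_rate=scaled(im.count_rate, 0.0),
                duration_mean=scaled(im.duration_mean, 1.0),
            )
        )
    return replace(spec, images=images)


def _draw_durations(
    n: int, mean: float, sd: float, family: str, rng: np.random.Generator
) -> np.ndarray:
    if family == "lognormal":
        # moment-matched: right-skewed like empirical fixation durations
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if family == "truncated-normal":
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    raise ValueError(f"unknown duration family {family!r}")


def generate_cohort(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[FixationDataset, np.ndarray]:
    """Draw a cohort; returns the dataset and per-fixation true cluster labels.

    Deterministic given the seed (``seed`` argument wins over ``spec.seed``).
    Record order: subjects (experts first), then images, then clusters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subjects = [(f"expert_{i + 1:02d}", 0) for i in range(spec.n_experts)] + [
        (f"layman_{i + 1:02d}", 1) for i in range(spec.n_laymen)
    ]
    records: list[FixationRecord] = []
    truth: list[int] = []
    for subject_id, g in subjects:
        group = GROUP_ORDER[g]
        for im in spec.images:
            for j in range(im.k_true):
                n = int(rng.poisson(im.count_rate[j, g]))
                if n == 0:
                    continue
                xy = rng.multivariate_normal(im.means[j], im.covs[j], size=n)
                # keep the cohort on-screen (tail mass clipped is negligible)
                xy[:, 0] = np.clip(xy[:, 0], 0.0, SCREEN_WIDTH)
                xy[:, 1] = np.clip(xy[:, 1], 0.0, SCREEN_HEIGHT)
                dur = _draw_durations(
                    n, im.duration_mean[j, g], im.duration_sd[j, g],
                    im.duration_family, rng,
                )
                for (x, y), d in zip(xy, dur):
                    records.append(
                        FixationRecord(subject_id, group, im.image_id,
                                       float(x), float(y), float(d))
                    )
                    truth.append(j)
    ds = FixationDataset(records, provenance=f"synthetic cohort (seed={seed})")
    return ds, np.asarray(truth, dtype=int)
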