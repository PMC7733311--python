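import numpy as np
import pytest

from gazeclass.io import FixationDataset, FixationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rng, n=30, subjects=("s1", "s2"), groups=("expert", "layman"),
                 images=("P1", "P2")):
    recs = []
    group_of = {s: groups[i % len(groups)] for i, s in enumerate(subjects)}
    for _ in range(n):
        s = subjects[int(rng.integers(len(subjects)))]
        recs.append(
            FixationRecord(
                subject_id=s,
                group=group_of[s],
                image_id=images[int(rng.integers(len(images)))],
                x=float(rng.uniform(0, 1920)),
                y=float(rng.uniform(0, 1200)),
                duration=float(rng.uniform(50, 400)),
            )
        )
    return recs


@pytest.fixture
def small_dataset(rng):
    return FixationDataset(make_records(rng), provenance="test")


@pytest.fixture
def two_blob_points(rng):
    """Two well-separated Gaussian clusters, 200 points each, unit covariance."""
    a = rng.normal(loc=(0.0, 0.0), scale=1.0, size=(200, 2))
    b = rng.normal(loc=(10.0, 0.0), scale=1.0, size=(200, 2))
    return np.vstack([a, b])
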