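import numpy as np
import pytest

from jsom import Dataset, SimSpec, generate_paired, shared_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset(rng):
    X = rng.normal(size=(20, 5))
    return Dataset(
        values=X,
        feature_names=[f"f{i}" for i in range(5)],
        cell_ids=[f"c{i}" for i in range(20)],
        labels=np.array(["A"] * 10 + ["B"] * 10),
    )


@pytest.fixture(scope="session")
def small_pair():
    """A well-separated synthetic pair small enough for fast training."""
    spec = SimSpec(
        k_clusters=3,
        cells_per_cluster1=60,
        cells_per_cluster2=60,
        p_shared=6,
        p_private1=2,
        p_private2=2,
        cluster_sep=6.0,
        shared_distortion=0.05,
        seed=42,
    )
    d1, d2, l1, l2 = generate_paired(spec)
    return spec, d1, d2, l1, l2, shared_spec(spec)
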