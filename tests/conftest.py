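import numpy as np
import pytest

from metabodl.io import FeatureTable


@pytest.fixture
def small_table() -> FeatureTable:
    """3 replicate groups x 2 replicates, 4 features, 2 missing cells."""
    values = np.array([
        [1.0, 10.0, 100.0, 5.0],
        [2.0, np.nan, 110.0, 6.0],
        [3.0, 30.0, 120.0, 7.0],
        [4.0, 40.0, np.nan, 8.0],
        [5.0, 50.0, 140.0, 9.0],
        [6.0, 60.0, 150.0, 10.0],
    ])
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(6)],
        feature_ids=["m1", "m2", "m3", "m4"],
        values=values,
        labels=["a", "a", "b", "b", "c", "c"],
        replicate_group=["ga", "ga", "gb", "gb", "gc", "gc"],
        batch=["x"] * 6,
        biomass=np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_table(rng: np.random.Generator, n: int = 5, p: int = 4,
                 missing: float = 0.0) -> FeatureTable:
    values = np.round(np.exp(rng.normal(0, 1, (n, p))), 6)
    if missing:
        values[rng.random((n, p)) < missing] = np.nan
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(p)],
        values=values,
        labels=[f"l{i % 2}" for i in range(n)],
        replicate_group=[f"g{i % 2}" for i in range(n)],
        biomass=np.round(np.exp(rng.normal(0, 0.2, n)), 6),
    )
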