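import numpy as np
import pandas as pd
import pytest

from rhizonet import OtuTable, SampleMetadata, SyntheticSpec


def flat_design(n_samples: int, factor: str = "group", levels=("a",)) -> SampleMetadata:
    """Minimal metadata: n samples cycled over the given factor levels."""
    ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    vals = [levels[i % len(levels)] for i in range(n_samples)]
    return SampleMetadata(pd.DataFrame({factor: vals}, index=ids))


def null_spec(n_otus: int, n_samples: int, depth: int = 10_000, seed: int = 0,
              **kwargs) -> SyntheticSpec:
    """Spec for an independent-OTU (null) table unless blocks/hubs given."""
    return SyntheticSpec(
        n_otus=n_otus, design=flat_design(n_samples), depth=depth, seed=seed,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """3 OTUs x 2 samples integer table."""
    df = pd.DataFrame(
        [[5, 0], [3, 7], [0, 2]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["S1", "S2"],
    )
    return OtuTable(df)


@pytest.fixture
def random_counts(rng):
    """30 OTUs x 10 samples random integer table."""
    counts = rng.integers(0, 200, size=(30, 10))
    df = pd.DataFrame(
        counts,
        index=[f"OTU_{i:02d}" for i in range(30)],
        columns=[f"S{j}" for j in range(10)],
    )
    return OtuTable(df)
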