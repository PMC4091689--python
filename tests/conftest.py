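import numpy as np
import pandas as pd
import pytest

from medusa.model import CountTable, SampleMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """3 features x 2 samples, hand-checkable."""
    data = pd.DataFrame(
        [[3, 0], [1, 5], [6, 5]],
        index=pd.Index(["fA", "fB", "fC"], name="feature_id"),
        columns=["s1", "s2"],
    )
    return CountTable(data)


@pytest.fixture
def random_counts(rng):
    def make(n_features=50, n_samples=8, max_count=200, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        data = pd.DataFrame(
            r.integers(0, max_count, size=(n_features, n_samples)),
            index=[f"f{i}" for i in range(n_features)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return CountTable(data.astype(np.int64))

    return make


@pytest.fixture
def visit_map():
    sm = SampleMap()
    for s, subj, visit in [
        ("a1", "A", 1), ("a2", "A", 2), ("a3", "A", 3),
        ("b1", "B", 1), ("c2", "C", 2), ("c3", "C", 3),
    ]:
        sm.sample_to_subject[s] = subj
        sm.sample_to_visit[s] = visit
    return sm
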