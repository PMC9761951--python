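import numpy as np
import pytest

from mdjl.io import OmicsDataset, SurvivalTable, ViewMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(rng, n=12, dims=(6, 5), with_missing=False):
    ids = [f"S{i}" for i in range(n)]
    views = []
    for v, d in enumerate(dims):
        vals = rng.standard_normal((d, n))
        if with_missing:
            miss = rng.uniform(size=vals.shape) < 0.08
            vals[miss] = np.nan
        views.append(ViewMatrix(f"view{v+1}", vals, [f"v{v}f{j}" for j in range(d)], list(ids)))
    time = rng.uniform(1.0, 50.0, size=n)
    event = (rng.uniform(size=n) < 0.7).astype(int)
    event[0] = 1  # guarantee at least one event
    return OmicsDataset(views, SurvivalTable(list(ids), time, event))


@pytest.fixture
def tiny_dataset(rng):
    return make_dataset(rng)
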