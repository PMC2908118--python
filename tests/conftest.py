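import numpy as np
import pytest

from metapatch import NBParams, PatchTimeSeries, pair_topology, square4_topology


@pytest.fixture
def study_params() -> NBParams:
    """The published parameter set: R = e, a = 0.1, S = 0.7, c = 1."""
    return NBParams(R=2.718, a=0.1, S=0.7, c=1.0, sigma=0.1)


@pytest.fixture
def pair():
    return pair_topology()


@pytest.fixture
def square4():
    return square4_topology()


def make_series(counts, replicate="rep1", patch="patch1", species="host",
                treatment="a", start_week=1.0):
    counts = np.asarray(counts, dtype=float)
    return PatchTimeSeries(
        replicate=replicate, patch=patch, species=species, treatment=treatment,
        weeks=start_week + np.arange(counts.size), counts=counts,
    )


@pytest.fixture
def series_factory():
    return make_series
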