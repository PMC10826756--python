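import numpy as np
import pytest

from outbreaklaw import PowerLaw
from outbreaklaw.io import OutbreakRecord, SizeFrequencyTable


@pytest.fixture(scope="session")
def pl_sample_sizes():
    """Fixed discrete power-law sample (alpha=2.15, xmin=1, n=10^4)."""
    rng = np.random.default_rng(20240215)
    return PowerLaw(2.15, 1).sample(10_000, rng)


@pytest.fixture(scope="session")
def pl_hist(pl_sample_sizes):
    return SizeFrequencyTable.from_sizes(pl_sample_sizes, (1998, 2017))


@pytest.fixture
def tiny_hist():
    """Hand-checkable histogram {1:5, 2:3, 3:2} over one year."""
    return SizeFrequencyTable(np.array([1, 2, 3]), np.array([5, 3, 2]), (2000, 2000))


@pytest.fixture
def records_mixed():
    return [
        OutbreakRecord(1998, 2),
        OutbreakRecord(1998, 2),
        OutbreakRecord(1998, 3),
        OutbreakRecord(2018, 1),
        OutbreakRecord(2019, 1500),
    ]
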