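import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gapseq import GenomicInterval, MappedRead

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(chrom: str, start: int, end: int, read_id: str = "") -> MappedRead:
    return MappedRead(GenomicInterval(chrom, start, end), read_id or f"r{start}_{end}")


@pytest.fixture
def read_factory():
    return make_read
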