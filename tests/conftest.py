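import numpy as np
import pytest
from hypothesis import settings

from tfea.intervals import GenomicRegion, SampleRegion

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample_region(
    chrom: str,
    start: int,
    stop: int,
    sample_id: str = "s1",
    condition_id: str = "c1",
) -> SampleRegion:
    return SampleRegion(GenomicRegion(chrom, start, stop), sample_id, condition_id)


@pytest.fixture
def sample_region_factory():
    return make_sample_region
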