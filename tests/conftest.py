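import numpy as np
import pytest

from nbclock.datatypes import MutationCall, SegmentProfile, TumorSample


@pytest.fixture
def tiny_sample():
    """Two diploid/trisomic segments with a handful of SNVs."""
    segments = [
        SegmentProfile("1", 0, 150_000_000, cn=2, b_allele=1),
        SegmentProfile("2", 0, 120_000_000, cn=3, b_allele=1),
    ]
    mutations = [
        MutationCall("1", 5_000_000, n_var=40, n_ref=40, segment_id=0),
        MutationCall("1", 9_000_000, n_var=38, n_ref=42, segment_id=0),
        MutationCall("2", 4_000_000, n_var=30, n_ref=60, segment_id=1),
    ]
    return TumorSample(sample_id="tiny", purity=1.0, ploidy=2.4,
                       segments=segments, mutations=mutations)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
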