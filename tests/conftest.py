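import numpy as np
import pandas as pd
import pytest

from breakgene.profiles_io import ProbeMap, Segment, SegmentedProfile


@pytest.fixture
def probe_map_small():
    """One chromosome, 40 probes at 1 kb spacing."""
    rows = [(f"p{i}", "1", (i + 1) * 1000) for i in range(40)]
    return ProbeMap(pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"]))


@pytest.fixture
def probe_map_two_chrom():
    rows = [(f"a{i}", "1", (i + 1) * 1000) for i in range(40)]
    rows += [(f"b{i}", "2", (i + 1) * 1000) for i in range(40)]
    return ProbeMap(pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"]))


def make_profile(sample_id, chrom_segments):
    """chrom_segments: {chrom: [(start, end, log2, call), ...]}"""
    return SegmentedProfile(sample_id, {
        c: [Segment(*s) for s in segs] for c, segs in chrom_segments.items()
    })


@pytest.fixture
def profile_three_segments(probe_map_small):
    """Neutral, gain, neutral: two real breakpoints."""
    return make_profile("S1", {"1": [
        (0, 9, 0.01, 0), (10, 24, 0.62, 1), (25, 39, -0.02, 0)]})
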