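import numpy as np
import pytest

from ripkit.patterns import PATTERNS
from ripkit.splice import SegmentSpan, GroundTruthTrack
from ripkit.synth import SynthParams


@pytest.fixture
def params():
    return SynthParams(seed=12345)


def make_track(n_segments, seg_len, sample_rate=50.0, pattern_cycle=PATTERNS):
    """A synthetic ground-truth track of equal-length segments cycling the
    pattern alphabet (signal-free; for exercising scorer/statistics code)."""
    spans = []
    labels = np.zeros(n_segments * seg_len, dtype=np.int8)
    for i in range(n_segments):
        pat = pattern_cycle[i % len(pattern_cycle)]
        s, e = i * seg_len, (i + 1) * seg_len
        spans.append(SegmentSpan(start=s, end=e, pattern=pat,
                                 source_id=f"s{i:05d}"))
        labels[s:e] = int(pat)
    return GroundTruthTrack(labels=labels, segment_table=spans,
                            sample_rate=sample_rate)
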