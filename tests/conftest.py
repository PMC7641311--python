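import numpy as np
import pytest

from ttkit.annotation import TranscriptionUnit
from ttkit.tracks import StrandedTrack


@pytest.fixture
def toy_tus():
    return [
        TranscriptionUnit("gA", "chr1", 1_000, 5_000, "+"),
        TranscriptionUnit("gB", "chr1", 8_000, 14_000, "-"),
        TranscriptionUnit("gC", "chr2", 2_000, 12_000, "+"),
    ]


@pytest.fixture
def constant_track():
    """Track with a chosen constant value over each toy TU span (plus margin)."""

    def _make(tus, value=1.0, margin=500):
        track = StrandedTrack({"chr1": 50_000, "chr2": 50_000})
        for tu, v in zip(tus, value if np.ndim(value) else [value] * len(tus)):
            lo = max(0, tu.start - margin)
            track.add_values(tu.chrom, tu.strand, lo, np.full(tu.end + margin - lo, float(v)))
        return track

    return _make
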