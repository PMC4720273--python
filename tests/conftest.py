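import numpy as np
import pytest

from hnsdiv.binding import CoverageTrack, IntensityTrack, RegionSet


@pytest.fixture
def intensity_from(request):
    def make(values):
        return IntensityTrack("chr", np.asarray(values, dtype=float))
    return make


def make_track(values, chrom="chr"):
    return CoverageTrack(chrom, np.asarray(values, dtype=float))


def make_regions(intervals, chrom="chr"):
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    return RegionSet(chrom, intervals, np.zeros(len(intervals)))


@pytest.fixture
def gaussian_intensity():
    """1e6 draws from the reference noise model Normal(0, 0.2)."""
    rng = np.random.default_rng(1234)
    return IntensityTrack("chr", rng.normal(0.0, 0.2, size=10 ** 6))
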