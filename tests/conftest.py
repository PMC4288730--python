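import numpy as np
import pytest

from fourc.digestion import FragmentMap
from fourc.profile import ViewpointProfile, ViewpointSpec
from fourc.simulate import SyntheticLocusSpec


@pytest.fixture
def default_spec() -> SyntheticLocusSpec:
    return SyntheticLocusSpec()


def uniform_map(chrom: str = "c", n: int = 100, fragment_length: int = 1000) -> FragmentMap:
    fmap = FragmentMap()
    fmap.add_chromosome(chrom, np.arange(n + 1, dtype=np.int64) * fragment_length)
    return fmap


@pytest.fixture
def uniform_fmap() -> FragmentMap:
    return uniform_map()


def make_profile(fmap: FragmentMap, counts, chrom: str = "c", position: int = 50_500) -> ViewpointProfile:
    vp = ViewpointSpec("vp", chrom, position, "ACG", "test")
    return ViewpointProfile(vp, fmap, np.asarray(counts, dtype=np.int64))
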