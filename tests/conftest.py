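import pytest

from regionkb.core import GenomicInterval, RegionSet
from regionkb.simulate import SimSpec, TOY_CHROM_SIZES, simulate_region_set


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


@pytest.fixture
def toy_pair():
    """A deterministic small pair of region sets on the toy genome."""
    A = simulate_region_set(SimSpec(n_regions=120, seed=101), label="A")
    B = simulate_region_set(SimSpec(n_regions=120, seed=102), label="B")
    return A, B


@pytest.fixture
def chrom_sizes():
    return dict(TOY_CHROM_SIZES)


@pytest.fixture
def tiny_sets():
    A = RegionSet([iv("chr1", 100, 200), iv("chr1", 300, 400)], label="A")
    B = RegionSet([iv("chr1", 150, 250)], label="B")
    return A, B
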