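import numpy as np
import pytest

from panelvar import PileupSite


def make_site(depth: int, alt: int, *, chrom: str = "chr1", pos: int = 100,
              alt_fwd: int | None = None, ref_fwd: int | None = None,
              offsets: tuple[int, ...] | None = None,
              true_vaf: float | None = None) -> PileupSite:
    """Construct a pileup with an even (or specified) strand split."""
    if alt_fwd is None:
        alt_fwd = alt // 2
    ref_total = depth - alt
    if ref_fwd is None:
        ref_fwd = ref_total // 2
    if offsets is None:
        offsets = tuple(range(alt))
    return PileupSite(
        chrom=chrom, pos=pos, ref_base="C", alt_base="T", depth=depth,
        alt_count=alt, alt_fwd=alt_fwd, alt_rev=alt - alt_fwd,
        ref_fwd=ref_fwd, ref_rev=ref_total - ref_fwd,
        alt_read_offsets=offsets, true_vaf=true_vaf)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
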