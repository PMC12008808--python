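import numpy as np
import pytest

from dichrom.model import Fiber, GenomicInterval


def make_fiber(
    fiber_id="f0",
    chrom="chr1",
    start=0,
    end=1000,
    m6a=(),
    nucleosomes=(),
    msps=(),
    cpg=None,
):
    """Small helper to build a fiber from plain tuples."""
    return Fiber(
        fiber_id,
        GenomicInterval(chrom, start, end),
        np.asarray(sorted(m6a), dtype=np.int64),
        [GenomicInterval(chrom, a, b) for a, b in nucleosomes],
        [GenomicInterval(chrom, a, b) for a, b in msps],
        dict(cpg or {}),
    )


@pytest.fixture
def fiber_factory():
    return make_fiber


def random_fiber(rng, chrom="chr1", span=2000, density=0.05, fiber_id=None):
    start = int(rng.integers(0, 500))
    end = start + span
    pos = np.flatnonzero(rng.random(span) < density) + start
    return make_fiber(
        fiber_id or f"r{rng.integers(1 << 30)}",
        chrom, start, end, m6a=pos.tolist(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
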