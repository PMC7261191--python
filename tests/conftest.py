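import numpy as np
import pytest

from promenh import AnchoredSequence, GenomicInterval, load_pwms


@pytest.fixture(scope="session")
def pwms():
    return load_pwms()


def make_anchored(seq: str, anchor_index: int, chrom: str = "chr1",
                  origin: int = 0, strand: str = "+") -> AnchoredSequence:
    """Wrap a raw string as a plus-strand anchored sequence for unit tests."""
    interval = GenomicInterval(chrom, origin, origin + len(seq), strand)
    return AnchoredSequence(interval=interval, anchor=origin + anchor_index, sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
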