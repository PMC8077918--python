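import numpy as np
import pytest

from wgscohort import GenomeSpec


@pytest.fixture
def small_genome() -> GenomeSpec:
    """Two 3-Mb chromosomes at 3-kb bins: 1000 bins each."""
    return GenomeSpec((("chr1", 3_000_000), ("chr2", 3_000_000)), 3000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
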