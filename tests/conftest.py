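import numpy as np
import pytest

from nearmedian import genome_from_chromosomes


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def make_genome():
    """Build a genome from signed circular chromosome lists."""

    def _make(*chroms, label=""):
        return genome_from_chromosomes(list(chroms), label=label)

    return _make
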