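import numpy as np
import pytest

from meicross import ChromosomeSpec, default_chromosomes


@pytest.fixture(scope="session")
def specs():
    return default_chromosomes()


@pytest.fixture
def single_chromosome():
    """One 15-Mb chromosome with a central-domain split, for focused tests."""
    return ChromosomeSpec(
        name="I", length_bp=15_000_000, center_start_bp=4_000_000,
        center_end_bp=11_000_000, pc_end="left",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
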