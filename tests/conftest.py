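import numpy as np
import pytest

from ecfuse.synthetic import SynthConfig, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def tiny_synth():
    """A small, fast dataset for unit tests (16 leaves x 4 proteins)."""
    cfg = SynthConfig(branching=(2, 2, 2, 2), proteins_per_leaf=4,
                      length_range=(18, 24), motif_len=7, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_split(tiny_synth):
    return split_dataset(tiny_synth, 0.25, np.random.default_rng(0))
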