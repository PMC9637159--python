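import numpy as np
import pytest

import spectgan as sg


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 phantom slices spanning levels and patterns (with neighbors)."""
    comp = sg.DatasetComposition(
        {
            (sg.Level.CER, sg.Pattern.NORMAL): 2,
            (sg.Level.BG, sg.Pattern.NORMAL): 2,
            (sg.Level.COR, sg.Pattern.NORMAL): 2,
            (sg.Level.BG, sg.Pattern.UNILATERAL): 2,
            (sg.Level.COR, sg.Pattern.UNILATERAL): 2,
            (sg.Level.COR, sg.Pattern.BILATERAL): 2,
        }
    )
    return sg.build_dataset(comp, rng_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
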