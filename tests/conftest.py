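import numpy as np
import pytest

from agestress.design import gen_design


@pytest.fixture
def small_design():
    """2 animals per cell: the smallest valid factorial cohort."""
    sizes = {(a, s): 2 for a in ("young", "aged") for s in ("control", "stress")}
    return gen_design(7, group_sizes=sizes, panel_sizes=sizes)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
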