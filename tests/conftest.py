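import numpy as np
import pytest

import milkcal as mc


@pytest.fixture(scope="session")
def default_groups():
    return mc.default_config()


@pytest.fixture(scope="session")
def group_by_label(default_groups):
    return {g.label: g for g in default_groups}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250930)
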