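import numpy as np
import pytest

from beecolony import ColonyParams, SimToggles, SURVIVAL_PRESETS


@pytest.fixture
def params():
    return ColonyParams()


@pytest.fixture
def params_III():
    return ColonyParams(survival=SURVIVAL_PRESETS["III"])


@pytest.fixture
def toggles_off():
    return SimToggles.all_off()


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)
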