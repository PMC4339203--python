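import numpy as np
import pytest


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def db8():
    from mnf3d.wavelet3d import daubechies8_filters

    return daubechies8_filters()
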