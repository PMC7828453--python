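import numpy as np
import pytest

import locomode as lm


@pytest.fixture(scope="session")
def small_recordings():
    """One 10 s recording per mode with the default profiles (fast fixture)."""
    return lm.simulate_recordings(10.0, 100.0, seed=42)


@pytest.fixture(scope="session")
def small_windows(small_recordings):
    return lm.windows_from_recordings(small_recordings, 200)


@pytest.fixture()
def xor_dataset():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    y = np.array([0, 1, 1, 0])
    return lm.Dataset(X, np.array(["Sit"] * 4, dtype=object), 200, y=y, n_classes=2)
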