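import numpy as np
import pytest

from chambervol import generate_eye_model


@pytest.fixture(scope="session")
def default_model():
    """Default synthetic eye (session-scoped: volume integration is costly)."""
    return generate_eye_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1729)
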