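import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic fully-germinated 640x640 dish scene."""
    from germinet.scenegen import SceneParams, generate_scene

    return generate_scene(SceneParams(germination_fraction=1.0, rng_seed=7))
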