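import numpy as np
import pytest

import kappacal as kc


@pytest.fixture(scope="session")
def remote_scene():
    return kc.remote_scene()


@pytest.fixture(scope="session")
def remote_frame(remote_scene):
    return kc.build_eyeball_frame(remote_scene.screen_corners, [-30.0, -70.0, 500.0])


@pytest.fixture(scope="session")
def noiseless_remote_9(remote_scene):
    """Nine exact binocular samples from the remote preset (seed 20240)."""
    return kc.generate_dataset(remote_scene, 9, 20240)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def flat_screen():
    """Axis-aligned screen in the plane z = 0 (identity eyeball frame)."""
    return np.array(
        [
            [-200.0, 100.0, 0.0],
            [200.0, 100.0, 0.0],
            [200.0, -100.0, 0.0],
            [-200.0, -100.0, 0.0],
        ]
    )
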