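import numpy as np
import pytest

import respvol as rv


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_clean():
    """Small, short clean phantom shared by fast tests."""
    cfg = rv.scenario("clean", shape=(60, 80), duration_s=6)
    seq, truth = rv.generate(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def arms_scene():
    """Torso-with-arms scene for the spatial-stage tests."""
    cfg = rv.scenario("arms_attached")
    seq, truth = rv.generate(cfg)
    return cfg, seq, truth


def dice(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
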