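import numpy as np
import pytest

import spikefield as sf


@pytest.fixture(scope="session")
def short_kin():
    """60 s of reach-and-grasp kinematics at 240 frames/s."""
    return sf.generate_kinematics(60.0, reach_rate_hz=0.4, seed=1)


@pytest.fixture(scope="session")
def tiny_session():
    """Small 2-unit session (60 s, coupling 0.5) shared by the unit tests."""
    truths = sf.population_truths(7, 2, coupling=0.5)
    return sf.generate_session(truths, 60.0, return_intensity=True)


@pytest.fixture(scope="session")
def tiny_blocks(tiny_session):
    return sf.build_blocks(tiny_session)
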