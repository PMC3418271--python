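import numpy as np
import pytest

from lungct import PhantomSpec, make_thorax_phantom


@pytest.fixture(scope="session")
def thorax_spec() -> PhantomSpec:
    """Default-geometry thorax phantom spec (200³, 35 µm, σ = 20 HU).

    The anatomical margins are tuned to the 10 px erosion radius at this
    grid size; generated once per session.
    """
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def thorax_phantom(thorax_spec):
    """(volumes, ground truth) for all 4 phases."""
    return make_thorax_phantom(thorax_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
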