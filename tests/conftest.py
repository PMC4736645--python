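import numpy as np
import pytest

from pglattice import SimulationParams


class ScriptedRng:
    """Stand-in random stream returning a scripted sequence of uniforms.

    Lets unit tests force a specific event path (mutate / don't mutate,
    move / stay, chosen lottery ticket) through the per-site operations.
    """

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


@pytest.fixture
def params3() -> SimulationParams:
    """3x3 toroidal lattice with the standard constants."""
    return SimulationParams(width=3, height=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
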