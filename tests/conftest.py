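import numpy as np
import pytest

from silkbeam import bpm, fibergen


@pytest.fixture(scope="session")
def small_population():
    """A modest comet-moth-density population reused by several tests."""
    return fibergen.sample_void_population(density=2.2, fiber_radius=8.0, seed=11)


@pytest.fixture(scope="session")
def small_cross_section(small_population):
    return fibergen.rasterize_cross_section(
        small_population, grid_spacing=bpm.default_grid_spacing(0.6), margin=5.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
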