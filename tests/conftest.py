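import numpy as np
import pytest

from fibromech import synth


@pytest.fixture
def cantilever():
    return synth.CantileverModel()


@pytest.fixture
def no_noise():
    return synth.NoiseModel.noiseless()


@pytest.fixture
def default_noise():
    return synth.NoiseModel()


@pytest.fixture
def small_design():
    """Tiny two-group cohort layout for fast end-to-end checks."""
    return synth.StudyDesign(
        groups=(
            synth.GroupSpec("control", 3, 21),
            synth.GroupSpec("chronic_d21", 3, 21),
        ),
        maps_per_specimen=2,
        grid_points=8,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
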