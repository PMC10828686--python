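import numpy as np
import pytest

from renalprog import synthetic
from renalprog.grading import GraderModel
from renalprog.preprocess import prepare_sample
from renalprog.survival import make_time_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid15():
    """The 15 x 200-day grid over a 3000-day horizon."""
    return make_time_grid(3000.0, 15)


@pytest.fixture(scope="session")
def tiny_grader():
    """Desk-scale grading network (every stage shrunk to 8 channels)."""
    return GraderModel(width_scale=0.02, depth_scale=0.1, seed=0)


@pytest.fixture(scope="session")
def phantom_samples():
    """Eight prepared phantom samples (two per grade) at 32^3."""
    samples = []
    for grade in (1, 2, 3, 4):
        for rep in range(2):
            vol, mask = synthetic.simulate_kidney_volume(
                grade, (48, 48, 48), seed=10 * grade + rep)
            samples.extend(prepare_sample(vol, mask, grade,
                                          f"g{grade}r{rep}",
                                          target=(32, 32, 32)))
    return samples
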