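import numpy as np
import pytest

from mrfit import DryingDataset, GeneratorConfig, generate_dataset

# cubic coefficients used throughout as a realistic ground truth
CUBIC_GAMMA = np.array([-4.0180, 12.5609, -11.1670, 3.5632])


@pytest.fixture
def toy_dataset():
    """Two-point dataset where gamma=[-1, 2] interpolates exactly."""
    return DryingDataset(shrinkage=[1.0, 0.5], moisture_ratio=[1.0, 0.0])


@pytest.fixture(scope="session")
def noisefree_cubic():
    """Noise-free cubic drying curve; the least-squares fit is exact."""
    ds, truth = generate_dataset(GeneratorConfig(sigma=0.0, kmax=60, seed=3))
    return ds


@pytest.fixture(scope="session")
def noisy_cubic():
    """Cubic drying curve with sigma=0.02 observation noise, kmax=100."""
    ds, truth = generate_dataset(GeneratorConfig(sigma=0.02, kmax=100, seed=11))
    return ds
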