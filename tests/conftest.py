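import numpy as np
import pytest

from nirnet.dataset import SpectralGrid
from nirnet.synthetic import BandSpec, GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def twoclass_dataset():
    """Small, clearly separable 2-class dataset on a 64-point grid."""
    config = GeneratorConfig(
        grid=SpectralGrid(4000.0, 8000.0, 64),
        n_classes=2,
        class_proportions=np.array([0.5, 0.5]),
        shared_bands=[BandSpec(6000.0, 400.0, 0.5)],
        class_bands=[[BandSpec(4800.0, 200.0, 0.3)], [BandSpec(7200.0, 200.0, 0.3)]],
        baseline_offset_sd=0.02,
        multiplicative_scatter_sd=0.02,
        noise_sd=0.01,
        n_samples=240,
        seed=42,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_multiclass_dataset():
    """Balanced 4-class dataset on a short grid for experiment smoke tests."""
    config = GeneratorConfig(
        grid=SpectralGrid(4000.0, 9000.0, 96),
        n_classes=4,
        class_proportions=np.full(4, 0.25),
        shared_bands=[BandSpec(6500.0, 500.0, 0.4)],
        class_bands=[
            [BandSpec(4500.0 + 1000.0 * c, 250.0, 0.3)] for c in range(4)
        ],
        baseline_offset_sd=0.02,
        multiplicative_scatter_sd=0.02,
        noise_sd=0.01,
        n_samples=320,
        seed=7,
    )
    return generate_dataset(config)
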