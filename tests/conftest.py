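import numpy as np
import pytest

from hsiquant import PipelineConfig, WavelengthAxis
from hsiquant.pipeline import _rois_from_truth, simulate_core


@pytest.fixture(scope="session")
def default_axis() -> WavelengthAxis:
    return WavelengthAxis(np.arange(500.0, 1002.5, 5.0))


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(seed=11, shape=(72, 72), n_cells=12)


@pytest.fixture(scope="session")
def noiseless_core(small_config):
    """One seeded noiseless synthetic core: (reflectance cube, ground truth)."""
    cube, truth, _layout = simulate_core(small_config, 0)
    return cube, truth


@pytest.fixture(scope="session")
def core_rois(noiseless_core):
    _cube, truth = noiseless_core
    return _rois_from_truth(truth.label_image)
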