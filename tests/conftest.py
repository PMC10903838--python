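import numpy as np
import pytest

from pronelung import Grid3D, LabelMap, Volume3D
from pronelung.analytics import AnalysisConfig
from pronelung.phantom import PhantomSpec, PoseParams, generate_phantom_pair
from pronelung.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def small_spec():
    """48^3 phantom spec covering the same physical extent as the default."""
    return PhantomSpec(shape=(48, 48, 48), spacing_mm=(6.0, 6.0, 6.0), seed=42)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_phantom_pair(small_spec)


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, pose-free pair with deformation: isolates the warp."""
    spec = PhantomSpec(
        shape=(48, 48, 48), spacing_mm=(6.0, 6.0, 6.0), seed=7,
        noise_sd_hu=0.0, pose=PoseParams(), deformation_amplitude_mm=12.0,
    )
    return generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def analysis_cfg_48():
    return AnalysisConfig(preprocess=PreprocessConfig(cube_side=48))


@pytest.fixture()
def unit_grid():
    return Grid3D((16, 16, 16), (1.0, 1.0, 1.0))


def make_volume(grid, value=0.0, unit="HU"):
    return Volume3D(grid, np.full(grid.shape, value, dtype=np.float32), unit)


def make_labelmap(grid, labels):
    return LabelMap(grid, np.asarray(labels, dtype=np.int16))
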