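import numpy as np
import pytest

from shgquant.optics import OpticalParameters, TissueSlab, optical_parameters


@pytest.fixture(scope="session")
def normal_slab() -> TissueSlab:
    return TissueSlab(
        thickness=100.0,
        excitation=optical_parameters("normal", 890),
        emission=optical_parameters("normal", 457),
        label="normal",
    )


@pytest.fixture(scope="session")
def cancer_slab() -> TissueSlab:
    return TissueSlab(
        thickness=100.0,
        excitation=optical_parameters("cancer", 890),
        emission=optical_parameters("cancer", 457),
        label="cancer",
    )


@pytest.fixture(scope="session")
def clear_slab() -> TissueSlab:
    """Scatter-free, absorption-free slab (ballistic limit)."""
    return TissueSlab(
        thickness=100.0,
        excitation=OpticalParameters(890, 0.0, 0.0, 0.0, 1.33),
        emission=OpticalParameters(457, 0.0, 0.0, 0.0, 1.33),
        label="clear",
    )


@pytest.fixture
def depths() -> np.ndarray:
    return np.arange(0.0, 81.0, 10.0)
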