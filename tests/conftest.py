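import numpy as np
import pytest

from refractsim import SchematicEye
from refractsim.fixtures import make_eye
from refractsim.grids import GridSpec


@pytest.fixture(scope="session")
def grid_2mm() -> GridSpec:
    return GridSpec(pupil_radius_mm=2.0, n_pupil=256, pad_factor=4)


@pytest.fixture(scope="session")
def grid_3mm() -> GridSpec:
    return GridSpec(pupil_radius_mm=3.0, n_pupil=256, pad_factor=4)


@pytest.fixture(scope="session")
def p1_eye() -> SchematicEye:
    """LOA-only eye needing plano -0.75 x 180, 2 mm pupil."""
    return SchematicEye(
        make_eye("P1_like", pupil_radius_mm=2.0), pupil_radius_mm=2.0
    )


@pytest.fixture(scope="session")
def emmetropic_eye() -> SchematicEye:
    return SchematicEye(
        make_eye("emmetrope", pupil_radius_mm=3.0), pupil_radius_mm=3.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
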