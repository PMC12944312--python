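import numpy as np
import pytest

from nirjoint.detector import DetectorSpec
from nirjoint.spectra import load_materials


@pytest.fixture(scope="session")
def materials():
    return load_materials()


@pytest.fixture(scope="session")
def detector_spec():
    """Default binned CCD centered on zero."""
    return DetectorSpec.centered(0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
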