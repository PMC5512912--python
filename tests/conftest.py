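import warnings

import numpy as np
import pytest

from iolens.eye_model import BUILTIN_NAMES, builtin_prescription

# Several fixtures (myopic eye, steep test surfaces) legitimately trigger the
# sag-coverage advisory; keep test output clean.
warnings.filterwarnings("ignore", message=".*real conic extent.*")


@pytest.fixture(params=BUILTIN_NAMES)
def builtin_eye(request):
    """Each packaged prescription in turn."""
    return builtin_prescription(request.param)


@pytest.fixture
def ga_6mm():
    return builtin_prescription("ga_6mm")


@pytest.fixture
def codev_6mm():
    return builtin_prescription("codev_6mm")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
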