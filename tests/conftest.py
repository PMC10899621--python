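import numpy as np
import pytest

from qpopscreen import (
    ScreenMeasurements,
    build_model_matrix,
    build_oacd,
    default_truth,
)


@pytest.fixture(scope="session")
def oacd10():
    """The 91-run composite design for the default 10-drug panel."""
    return build_oacd(10, default_truth().names)


@pytest.fixture(scope="session")
def oacd10_matrix(oacd10):
    return build_model_matrix(oacd10)


def make_screen(design, y, replicates=1):
    """Wrap a per-run response vector as ScreenMeasurements."""
    y = np.asarray(y, dtype=float)
    return ScreenMeasurements(design, [np.full(replicates, v) for v in y])
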