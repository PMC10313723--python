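import warnings

import numpy as np
import pytest

from pdeclosure.adjoint import TrainingData
from pdeclosure.closures import LinearClosure
from pdeclosure.waves import SolitonParams, kdv_library, kdv_two_soliton, make_kdv_system

warnings.filterwarnings("ignore", message="negative biological concentration")


@pytest.fixture(scope="session")
def soliton_params():
    return SolitonParams()


@pytest.fixture(scope="session")
def kdv_small_data(soliton_params):
    """Analytic two-soliton snapshots on a coarse grid for fast solves."""
    sysm = make_kdv_system("lowfi", Nx=64)
    x = sysm.grid.x
    tt = np.round(np.arange(0.0, 0.2001, 0.02), 10)
    states = np.stack([kdv_two_soliton(x, t, soliton_params)[:, None] for t in tt])
    return TrainingData(tt, states)


@pytest.fixture()
def kdv_closure_system():
    closure = LinearClosure(kdv_library())
    closure.set_params(np.array([0.05, -0.5, -2.0, 0.1]))
    return make_kdv_system("closure", Nx=64, closure=closure), closure
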