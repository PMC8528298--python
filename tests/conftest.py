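import numpy as np
import pytest

from optocardiax import ionic_models as im
from optocardiax.chr2 import ChR2Params


@pytest.fixture(scope="session")
def healthy():
    return im.make_healthy_params()


@pytest.fixture(scope="session")
def caf():
    return im.make_caf_params()


@pytest.fixture(scope="session")
def healthy_rest(healthy):
    return im.equilibrate_rest(healthy).as_array()


@pytest.fixture(scope="session")
def caf_rest(caf):
    return im.equilibrate_rest(caf).as_array()


@pytest.fixture(scope="session")
def chr2_defaults():
    return ChR2Params()


def paced_trace(params, beats=5, cl=1000.0, amp=20.0, dur=2.0, dt=0.02,
                cell=None, E_e=0.0, record_every=5):
    """1 Hz-paced 0D voltage trace used across test modules."""
    from optocardiax._kernels import run_zero_d

    n = int(round(beats * cl / dt))
    t = np.arange(n) * dt
    stim = np.where((t % cl) < dur, amp, 0.0)
    ee = np.full(n, E_e)
    cell = im.initial_state().as_array().copy() if cell is None else cell.copy()
    ch = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    tt, V = run_zero_d(cell, ch, params, ChR2Params(), dt, stim, ee,
                       record_every=record_every)
    return tt, V, cell
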