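import numpy as np
import pytest

from ssfp_motion import (
    McConfig,
    PulsatilityModel,
    pulsatility_trace,
    reference_sequence,
    reference_tissue,
    rigid_body_trace,
    simulate_mc_signal,
    simulate_timeseries,
)
from ssfp_motion.synthetic import _rigid_reference, fig3_gradient_direction


@pytest.fixture(scope="session")
def seq200():
    return reference_sequence(n_tr=200)


@pytest.fixture(scope="session")
def tissue():
    return reference_tissue(D=1.0e-3)


@pytest.fixture(scope="session")
def pulsatile_model():
    return PulsatilityModel(v_card=0.4, heart_rate=50.0)


@pytest.fixture(scope="session")
def pulsatile_trace200(seq200, pulsatile_model):
    return pulsatility_trace(pulsatile_model, 1.0, seq200.TR, seq200.n_tr)


@pytest.fixture(scope="session")
def pulsatile_epg(seq200, tissue, pulsatile_trace200):
    return simulate_timeseries(seq200, tissue, pulsatile_trace200)


@pytest.fixture(scope="session")
def rigid_setup(seq200):
    """(sequence with decoded gradient direction, motion, velocity trace)."""
    g = fig3_gradient_direction()
    seq = seq200.with_(g_hat=g)
    motion = _rigid_reference()
    trace = rigid_body_trace(motion, g, seq.TR, seq.n_tr)
    return seq, motion, trace


@pytest.fixture(scope="session")
def mc_pulsatile_full(seq200, tissue, pulsatile_model):
    """Monte-Carlo pulsatile signal at the full reference size (1e5 spins)."""
    cfg = McConfig(seq=seq200, tissue=tissue, motion=pulsatile_model,
                   n_spins=100_000, steps_per_tr=100, seed=101)
    return simulate_mc_signal(cfg)


@pytest.fixture(scope="session")
def steady_state_magnitude(seq200, tissue):
    """Motion-free steady-state magnitude (sets the noise scale for SNR)."""
    return abs(simulate_timeseries(seq200, tissue).values[-1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
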