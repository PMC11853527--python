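import numpy as np
import pytest

from hv1kit.synthetic import ChannelModelParams, VoltageProtocol, simulate_family


@pytest.fixture
def wt_params():
    """Noiseless WT-like channel."""
    return ChannelModelParams()


def full_curve_protocol(params: ChannelModelParams, v_lo=-10, v_hi=90, dv=10,
                        sample_rate=500.0, pH_o=6.5, pH_i=6.5):
    """Pulse family spanning the g-V curve; durations scale with tau_act so
    the exponential fit sees several time constants at every voltage."""
    steps = [(float(V), max(5 * params.tau_act(V) + params.delay, 1.0))
             for V in range(v_lo, v_hi, dv)]
    return VoltageProtocol(steps=steps, sample_rate=sample_rate,
                           pH_o=pH_o, pH_i=pH_i)


def low_po_protocol(params: ChannelModelParams, po_max=0.01, n=7, dv=2.0,
                    sample_rate=500.0, pH_o=6.5, pH_i=6.5):
    """2 mV-step protocol confined to open probabilities below ``po_max``,
    for limiting-slope work.  A pH gradient moves the reversal potential
    away from the fit window so the low-conductance currents keep a usable
    driving force."""
    k = params.k_gen
    v_hi = params.v_half(pH_o, pH_i) - k * np.log(1.0 / po_max - 1.0)
    vs = v_hi - dv * np.arange(n)[::-1]
    steps = [(float(V), max(5 * params.tau_act(V) + params.delay, 1.0))
             for V in vs]
    return VoltageProtocol(steps=steps, sample_rate=sample_rate,
                           pH_o=pH_o, pH_i=pH_i)


@pytest.fixture
def wt_family(wt_params):
    return simulate_family(wt_params, full_curve_protocol(wt_params))
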