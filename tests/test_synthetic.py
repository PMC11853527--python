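"""Generator invariants: Boltzmann steady states, Nernst consistency,
pH-shift displacement, leak arithmetic, and seeded determinism."""

import numpy as np
import pytest

from hv1kit.constants import nernst_slope_mv
from hv1kit.gating import build_gv, fit_boltzmann
from hv1kit.selectivity import nernst_potential
from hv1kit.synthetic import (ChannelModelParams, ExchangeEvent,
                              VoltageProtocol, WaterSpec,
                              generate_mutation_table, generate_toy_ensemble,
                              simulate_family, simulate_leak_experiment)
from hv1kit.traces import activation_taus

from conftest import full_curve_protocol


def test_steady_current_at_vhalf_is_half_activation():
    """A long noiseless pulse to V_half settles at Po = 0.5, so the steady
    current is (g_leak + g_max/2)*(V_half - E_H)."""
    p = ChannelModelParams(g_leak=0.1)
    proto = VoltageProtocol(steps=[(p.V_half_ref, 60.0)], sample_rate=200.0)
    fam = simulate_family(p, proto)
    tr = fam.traces[0]
    steady = tr.step_segment().I[-1]
    expected = (p.g_leak + p.g_max / 2) * (p.V_half_ref - 0.0)
    assert steady == pytest.approx(expected, rel=1e-4)


def test_dpH_displaces_po_curve_by_shift_slope():
    p = ChannelModelParams()
    # dpH = -1 (pH_o one unit below pH_i) shifts the curve positively
    assert p.v_half(5.5, 6.5) - p.v_half(6.5, 6.5) == pytest.approx(
        p.pH_shift_slope)
    V = np.linspace(-60, 120, 50)
    po_sym = p.po_inf(V, 6.5, 6.5)
    po_acid = p.po_inf(V + p.pH_shift_slope, 5.5, 6.5)
    np.testing.assert_allclose(po_sym, po_acid, rtol=1e-12)


def test_null_channel_is_silent():
    p = ChannelModelParams(g_max=0.0, g_leak=0.0, noise_sd=0.0)
    fam = simulate_family(p, VoltageProtocol(steps=[(40.0, 2.0)]))
    assert np.all(fam.traces[0].I == 0.0)


def test_simulated_gv_round_trips_through_boltzmann(wt_params, wt_family):
    """Noiseless g(V) = g_max*Po_inf(V) satisfies the Boltzmann relation
    exactly: the fitter recovers V_half and k to 0.1%."""
    gv = build_gv(activation_taus(wt_family), V_rev=0.0)
    fit = fit_boltzmann(gv)
    assert fit.V_half == pytest.approx(wt_params.V_half_ref, abs=0.021)
    assert fit.k == pytest.approx(wt_params.k_gen, rel=1e-3)
    assert fit.g_max == pytest.approx(wt_params.g_max, rel=1e-3)


def test_open_channel_reverses_at_nernst_potential():
    """The simulated zero-current voltage of an open channel equals E_H to
    below 0.1 mV."""
    p = ChannelModelParams(V_half_ref=-120.0, delay=0.0)  # open everywhere
    E_H = nernst_potential(7.5, 6.5)
    proto = full_curve_protocol(p, v_lo=-70, v_hi=-45, dv=5, pH_o=7.5, pH_i=6.5)
    fam = simulate_family(p, proto)
    V = np.array([tr.V_test for tr in fam])
    I = np.array([tr.step_segment().I[-1] for tr in fam])
    v0 = np.interp(0.0, I, V)
    assert v0 == pytest.approx(E_H, abs=0.1)


def test_step_shorter_than_three_samples_rejected():
    p = ChannelModelParams()
    with pytest.raises(ValueError, match="unresolvable"):
        simulate_family(p, VoltageProtocol(steps=[(40.0, 0.002)],
                                           sample_rate=1000.0))


def test_family_determinism_under_seed():
    p = ChannelModelParams(noise_sd=2.0, seed=42)
    proto = VoltageProtocol(steps=[(40.0, 1.0)])
    a = simulate_family(p, proto)
    b = simulate_family(p, proto)
    np.testing.assert_array_equal(a.traces[0].I, b.traces[0].I)


class TestLeakExperiment:
    def test_holding_current_shift_is_ohmic(self):
        """0.05 nS leak, pH_o 6.5 -> 5.5 at V_hold = -40 mV: E_H steps from
        0 to +58.3 mV so I_hold shifts by 0.05*(-58.3) = -2.9 pA inward."""
        p = ChannelModelParams(g_leak=0.05, noise_sd=0.0, V_half_ref=60.0)
        proto = VoltageProtocol(steps=[(10.0, 1.0)], V_hold=-40.0,
                                sample_rate=100.0)
        rec = simulate_leak_experiment(p, proto, [ExchangeEvent(40.0, 5.5)])
        t, I = rec.trace.t, rec.trace.I
        before = I[(t > 38) & (t < 39.9)].mean()
        after = I[(t > 40.2) & (t < 42)].mean()
        expected = -0.05 * nernst_slope_mv()
        assert after - before == pytest.approx(expected, rel=1e-3)

    def test_no_leak_no_shift(self):
        p = ChannelModelParams(g_leak=0.0, noise_sd=0.0, V_half_ref=60.0)
        proto = VoltageProtocol(steps=[(10.0, 1.0)], V_hold=-40.0,
                                sample_rate=100.0)
        rec = simulate_leak_experiment(p, proto, [ExchangeEvent(40.0, 5.5)])
        t, I = rec.trace.t, rec.trace.I
        assert I[(t > 38) & (t < 39.9)].mean() == pytest.approx(
            I[(t > 40.2) & (t < 42)].mean(), abs=1e-6)

    def test_same_pH_exchange_shifts_nothing(self):
        p = ChannelModelParams(g_leak=0.1, noise_sd=0.0, V_half_ref=60.0)
        proto = VoltageProtocol(steps=[(10.0, 1.0)], V_hold=-40.0,
                                sample_rate=100.0)
        rec = simulate_leak_experiment(p, proto, [ExchangeEvent(40.0, 6.5)])
        t, I = rec.trace.t, rec.trace.I
        assert I[(t > 38) & (t < 39.9)].mean() == pytest.approx(
            I[(t > 40.2) & (t < 42)].mean(), abs=1e-9)

    def test_overlapping_exchanges_rejected(self):
        p = ChannelModelParams()
        proto = VoltageProtocol(steps=[(10.0, 1.0)])
        with pytest.raises(ValueError, match="overlapping"):
            simulate_leak_experiment(p, proto, [ExchangeEvent(5.0, 5.5),
                                                ExchangeEvent(5.0, 7.5)])


class TestMutationTable:
    def test_hotspot_positions_confined(self):
        recs = generate_mutation_table(273, 0, [(200, 10, 50)], seed=1)
        assert len(recs) == 50
        assert all(190 <= r.position <= 210 for r in recs)

    def test_pure_missense_probs(self):
        from hv1kit.hotspot import classify
        recs = generate_mutation_table(273, 40, class_probs=(1.0, 0.0, 0.0),
                                       seed=2)
        assert all(classify(r) == "missense" for r in recs)

    def test_determinism(self):
        a = generate_mutation_table(273, 30, [(50, 5, 10)], seed=7)
        b = generate_mutation_table(273, 30, [(50, 5, 10)], seed=7)
        assert a == b

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            generate_mutation_table(273, 10, class_probs=(0.5, 0.1, 0.1))


class TestToyEnsemble:
    def test_displacement_recovered(self):
        from hv1kit.geometry import axial_shift
        d, a = generate_toy_ensemble(40, displacement_z=7.0, seed=3)
        assert axial_shift(d, a, [208]) == pytest.approx(7.0, abs=0.1)

    def test_zero_jitter_zero_displacement_identical(self):
        from hv1kit.geometry import rmsd_series
        d, a = generate_toy_ensemble(5, 0.0, jitter_sd=0.0, seed=4)
        np.testing.assert_array_equal(d.coords, a.coords)
        assert np.all(rmsd_series(d, d.frame(0)) < 1e-12)

    def test_negative_frames_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_ensemble(0, 1.0)

    def test_water_slab_exclusion(self):
        d, _ = generate_toy_ensemble(10, 0.0,
                                     waters=WaterSpec(exclusion_halfwidth=2.25),
                                     seed=5)
        widx = d.select(resnames=["HOH"])
        z = d.coords[:, widx, 2]
        assert widx.size > 0
        assert np.all(np.abs(z) >= 2.25)
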