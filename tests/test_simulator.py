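import math

import numpy as np
import pytest

from ivlsim.simulator import (CurrentStep, SimulationError, StimulusProtocol,
                              VoltageClamp, electrotonic_profile, rheobase,
                              simulate, spike_count)
from ivlsim.synapses import PlacedSynapse, SynapseBank

from conftest import passive_chain


def test_passive_step_matches_rc_closed_form(single_passive):
    morph, channels, p = single_passive
    i_pa = 20.0
    proto = StimulusProtocol(duration=5 * p["tau_ms"], dt=0.025,
                             steps=[CurrentStep("S", i_pa)],
                             record_sites=["S"])
    tr = simulate(morph, channels, proto)
    for t in (p["tau_ms"], 5 * p["tau_ms"]):
        k = int(round(t / 0.025))
        exact = -70.0 + i_pa * 1e-3 * p["r_in_mohm"] * (1 - math.exp(-t / p["tau_ms"]))
        assert tr.voltage[0][k] == pytest.approx(exact, rel=0.01)


def test_passive_input_resistance_and_time_constant(single_passive):
    """Steady-state deflection gives R_in = 1/(g_leak area); 63.2% point gives tau."""
    morph, channels, p = single_passive
    i_pa = 10.0
    proto = StimulusProtocol(duration=8 * p["tau_ms"],
                             steps=[CurrentStep("S", i_pa)], record_sites=["S"])
    tr = simulate(morph, channels, proto)
    v = tr.voltage[0]
    dv_inf = v[-1] - v[0]
    r_in = dv_inf / (i_pa * 1e-3)
    assert r_in == pytest.approx(p["r_in_mohm"], rel=0.01)
    k63 = np.argmax(v - v[0] >= dv_inf * (1 - math.exp(-1)))
    assert tr.time[k63] == pytest.approx(p["tau_ms"], rel=0.01)


def test_zero_conductance_voltage_stays_constant(single_passive):
    morph, channels, _ = single_passive
    channels = channels.copy()
    channels.densities = {"leak": {"soma": 0.0}}
    proto = StimulusProtocol(duration=20.0, record_sites=["S"], v_init=-55.0)
    tr = simulate(morph, channels, proto)
    assert np.all(tr.voltage[0] == -55.0)


def test_charge_balance_at_every_compartment(cell1):
    """Capacitive + ionic + synaptic + axial + injected currents cancel.

    The solver records currents at the Crank-Nicolson midpoint, so the
    discrete balance holds to round-off relative to the current scale.
    """
    morph, channels = cell1.morphology, cell1.channels
    bank = SynapseBank([
        PlacedSynapse("PYR", 5, 2.4, 12.7, 0.0, 3e-4, np.array([20.0, 60.0])),
        PlacedSynapse("IS3", 12, 1.6, 12.0, -80.0, 3e-4, np.array([35.0])),
    ])
    proto = StimulusProtocol(duration=100.0, dt=0.025,
                             steps=[CurrentStep("S", 80.0)],
                             synapses=bank, record_sites="all")
    tr = simulate(morph, channels, proto)
    dt = proto.dt
    c_nf = np.array([c.specific_capacitance for c in morph.compartments]) \
        * morph.areas * 1e-5
    g_ax = morph.axial_conductances()
    v = tr.voltage  # (n, nt)
    v_mid = 0.5 * (v[:, 1:] + v[:, :-1])
    i_mem = tr.currents.sum(axis=1)[:, 1:] * 1e-3  # nA, at midpoints
    i_cap = c_nf[:, None] * np.diff(v, axis=1) / dt
    i_ax = np.zeros_like(v_mid)
    for i in range(1, morph.n):
        p = morph.parent_index[i]
        flow = g_ax[i] * (v_mid[p] - v_mid[i])
        i_ax[i] += flow
        i_ax[p] -= flow
    i_inj = np.zeros_like(v_mid)
    i_inj[0] = 80.0 * 1e-3
    residual = i_cap + i_mem - i_ax - i_inj
    scale = np.max(np.abs(i_mem)) + np.max(np.abs(i_cap))
    assert np.max(np.abs(residual)) / scale < 1e-6


def test_gating_variables_stay_in_unit_interval(cell1):
    from ivlsim.simulator import resting_state
    state = resting_state(cell1.morphology, cell1.channels, settle=300.0)
    for key in ("m", "h"):
        assert np.all(state[key] >= 0.0)
        assert np.all(state[key] <= 1.0)


def test_self_convergence_on_halved_step(cell1):
    morph, channels = cell1.morphology, cell1.channels
    traces = {}
    for dt in (0.025, 0.0125):
        proto = StimulusProtocol(duration=120.0, dt=dt,
                                 steps=[CurrentStep("S", 20.0)],
                                 record_sites=["S"])
        traces[dt] = simulate(morph, channels, proto)
    coarse = traces[0.025].voltage[0]
    fine = traces[0.0125].voltage[0][::2]
    assert np.max(np.abs(coarse - fine)) < 0.05  # subthreshold protocol, mV


def test_clamp_at_synaptic_reversal_gives_zero_synaptic_current(cell1):
    morph = cell1.morphology
    channels = cell1.channels.passive_only(e_leak=0.0)
    bank = SynapseBank([PlacedSynapse("IS3", 0, 1.6, 12.0, 0.0, 5e-4,
                                      np.array([10.0]))])
    proto = StimulusProtocol(duration=60.0, clamp=VoltageClamp("S", 0.0),
                             synapses=bank, record_sites=["S"], v_init=0.0)
    tr = simulate(morph, channels, proto)
    syn = tr.current("S", "syn_exc")
    assert np.max(np.abs(syn)) < 1e-9


def test_divergence_reports_time_and_compartment(single_passive):
    """A runaway membrane (leak reversal far outside the physical range)
    aborts with the offending time and compartment in the message."""
    from ivlsim.channels import ChannelSet, ChannelSpec, GatingScheme
    morph, _, _ = single_passive
    runaway = ChannelSet({"leak": ChannelSpec("leak", 1000.0,
                                              GatingScheme(0, 0))},
                         {"leak": {"soma": 50.0}})
    with pytest.raises(SimulationError, match="compartment 0"):
        simulate(morph, runaway, StimulusProtocol(duration=50.0,
                                                  record_sites=["S"]))


def test_clamp_and_injection_same_site_rejected():
    with pytest.raises(ValueError):
        StimulusProtocol(duration=10.0, steps=[CurrentStep("S", 10.0)],
                         clamp=VoltageClamp("S", -60.0))


class TestElectrotonicProfile:
    def test_injection_site_attenuation_is_zero(self):
        morph, channels = passive_chain(n=20)
        att = electrotonic_profile(morph, channels, "out_of_soma")
        assert att[0] == 0.0
        att_in = electrotonic_profile(morph, channels, "into_soma")
        assert att_in[morph.terminals()[0]] == 0.0

    def test_uniform_cable_matches_cosh_solution(self):
        n, length, diam, leak, ra = 50, 8.0, 2.0, 0.05, 150.0
        morph, channels = passive_chain(n=n, length=length, diameter=diam,
                                        leak=leak, ra=ra)
        att = electrotonic_profile(morph, channels, "out_of_soma")
        r_m = 1.0 / (leak * 1e-12 * 1e8)  # Ohm cm^2
        lam = math.sqrt((r_m / ra) * (diam * 1e-4 / 4.0)) * 1e4  # um
        cable_l = (n + 1) * length
        x0 = length / 2.0
        for i in range(1, n + 1):
            x = morph.path_distance[i] - length / 2.0
            expect = (math.cosh((cable_l - x) / lam)
                      / math.cosh((cable_l - x0) / lam))
            assert 10 ** (-att[i]) == pytest.approx(expect, rel=0.02)

    def test_vanishing_axial_resistance_is_isopotential(self):
        morph, channels = passive_chain(n=20, ra=1e-6)
        att = electrotonic_profile(morph, channels, "out_of_soma")
        assert np.max(np.abs(att)) < 1e-6

    def test_large_amplitude_rejected(self):
        morph, channels = passive_chain(n=5)
        with pytest.raises(ValueError, match="amplitude"):
            electrotonic_profile(morph, channels, amplitude=20.0)


class TestRheobase:
    def test_passive_model_never_spikes(self):
        morph, channels = passive_chain(n=3)
        with pytest.raises(SimulationError):
            rheobase(morph, channels, (0.0, 200.0), duration=200.0)

    def test_bisection_postcondition(self, cell1):
        from ivlsim.simulator import resting_state
        i_star = cell1.find_rheobase()
        morph, channels = cell1.morphology, cell1.channels
        state = resting_state(morph, channels, settle=200.0)

        def spikes(i_pa):
            proto = StimulusProtocol(duration=1000.0,
                                     steps=[CurrentStep("S", i_pa)],
                                     record_sites=["S"])
            tr = simulate(morph, channels, proto, initial_state=state)
            return spike_count(tr, "S") >= 1

        assert spikes(i_star)
        assert not spikes(i_star - 1.0)

    def test_non_bracketing_range_rejected(self, cell1):
        with pytest.raises(SimulationError):
            rheobase(cell1.morphology, cell1.channels, (200.0, 300.0),
                     duration=300.0)
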