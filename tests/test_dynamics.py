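"""Closed-form primitives and the assembled network derivative."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cpgsim import (
    ChannelSpec,
    Depression,
    ElectricalSynapseSpec,
    GateSpec,
    IonPoolSpec,
    NetworkValueError,
    RegulationLink,
    RuntimeNetwork,
    assemble_derivative,
    channel_current,
    chemical_current,
    depression_derivative,
    depression_event_update,
    dual_exp_norm,
    dual_exp_peak_time,
    electrical_current,
    gate_derivative,
    gate_inf,
    m2_derivative,
    make_fixture,
    pool_derivative,
    regulation_factor,
    synapse_m1,
)
from cpgsim.integrators import integrate_fixed
from cpgsim.schema_io import (
    CompartmentSpec,
    NetworkSpec,
    NeuronSpec,
    SimulationConfig,
    VoltageDependence,
)


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------

def test_gate_inf_examples():
    assert gate_inf(-40.0, -40.0, 5.0) == pytest.approx(0.5)
    assert gate_inf(-35.0, -40.0, 5.0) == pytest.approx(1 / (1 + math.exp(-1)))
    assert gate_inf(-35.0, -40.0, 5.0) == pytest.approx(0.73106, abs=1e-5)
    assert gate_inf(50.0, -40.0, -5.0) < 1e-7  # falling sigmoid limit
    with pytest.raises(NetworkValueError):
        gate_inf(0.0, 0.0, 0.0)


@given(st.floats(-120, 60), st.floats(-120, 60))
def test_gate_inf_monotone(v1, v2):
    if v1 == v2:
        return
    lo, hi = sorted((v1, v2))
    assert gate_inf(hi, -40.0, 6.0) >= gate_inf(lo, -40.0, 6.0)   # rising
    assert gate_inf(hi, -40.0, -6.0) <= gate_inf(lo, -40.0, -6.0)  # falling


def test_gate_derivative_fixed_point_and_rate():
    g = GateSpec(h=-40.0, s=5.0, tau=0.1)
    V = -37.0
    assert gate_derivative(gate_inf(V, g.h, g.s), V, g) == pytest.approx(0.0)
    g2 = GateSpec(h=-40.0, s=5.0, tau=0.1)
    # A = 0 with A∞ → 1 at very depolarised V: rate (1-0)/0.1 = 10 s⁻¹
    assert gate_derivative(0.0, 100.0, g2) == pytest.approx(10.0, rel=1e-6)


def test_gate_relaxation_matches_exponential():
    """At fixed V a gate relaxes as A∞ + (A0−A∞)e^(−t/τ) (linear-ODE oracle)."""
    gate = GateSpec(h=-40.0, s=5.0, tau=0.05)
    ch = ChannelSpec("probe", gbar=0.0, E=0.0, activation=gate, p=1)
    cell = NeuronSpec("H", (CompartmentSpec(
        "soma", Cm=1.0, channels=(ChannelSpec("leak", 1.0, -50.0), ch),
        V_init=-50.0),))
    spec = NetworkSpec((cell,), sim=SimulationConfig(duration=0.5))
    rt = RuntimeNetwork(spec)
    stt = rt.initial_state()
    stt.gates[:] = 0.0  # start the gate away from its fixed point
    _, times, snaps, _, _ = integrate_fixed(rt, stt, 0.3, 2e-5,
                                            "semi_implicit_cn", record_stride=100)
    A = snaps[:, rt.nc]  # first gate
    Ainf = gate_inf(-50.0, gate.h, gate.s)
    exact = Ainf * (1.0 - np.exp(-times / gate.tau))
    assert np.max(np.abs(A - exact)) < 1e-6


def test_voltage_dependent_tau():
    from cpgsim import gate_tau

    g = GateSpec(h=0.0, s=5.0, tau_base=0.01, tau_amp=0.04, tau_h=-40.0,
                 tau_s=10.0)
    assert gate_tau(-40.0, g) == pytest.approx(0.01 + 0.02)
    assert gate_tau(-200.0, g) == pytest.approx(0.01, rel=1e-5)
    assert gate_tau(100.0, g) == pytest.approx(0.05, rel=1e-3)


# ---------------------------------------------------------------------------
# channels, pools, regulation
# ---------------------------------------------------------------------------

def test_channel_current_substitution():
    ch = ChannelSpec("x", gbar=2.0, E=-70.0, activation=GateSpec(0, 1, 1e-3), p=1)
    assert channel_current(-70.0, ch, A=1.0) == pytest.approx(0.0)
    assert channel_current(-50.0, ch, A=1.0) == pytest.approx(40.0)
    ch2 = ChannelSpec("y", gbar=1.0, E=0.0,
                      activation=GateSpec(0, 1, 1e-3), p=3,
                      inactivation=GateSpec(0, -1, 1e-3), q=1)
    full = channel_current(-50.0, ch2, A=1.0, B=1.0)
    gated = channel_current(-50.0, ch2, A=0.5, B=0.5)
    assert gated == pytest.approx(full * 0.5 ** 3 * 0.5)


def test_pool_derivative_forms():
    pool = IonPoolSpec("Ca", k1=2.0, k2=1.0)
    assert pool_derivative(0.3, 0.0, pool) == pytest.approx(-2.0 * 0.3)
    # steady state at c = −k2·I for inward current: k2·I = −0.5 ⇒ c* = 0.5
    assert pool_derivative(0.5, -0.5, pool) == pytest.approx(0.0)


def test_pool_charging_matches_closed_form():
    """Constant source current: c(t) = c*(1−e^(−k1·t)) (linear-ODE oracle)."""
    # ungated channel at (stiffly clamped) fixed V supplies a constant
    # inward current; the huge leak pins V at −60 to within ~1 µV
    ch = ChannelSpec("src", gbar=0.01, E=40.0, feeds_pool="Ca")
    pool = IonPoolSpec("Ca", k1=4.0, k2=0.5, source_channels=("src",))
    cell = NeuronSpec("P", (CompartmentSpec(
        "soma", Cm=1.0, channels=(ChannelSpec("leak", 1000.0, -60.0), ch),
        pools=(pool,), V_init=-60.0),))
    spec = NetworkSpec((cell,), sim=SimulationConfig(duration=2.0))
    rt = RuntimeNetwork(spec)
    stt = rt.initial_state()
    _, times, snaps, _, _ = integrate_fixed(rt, stt, 1.5, 1e-5,
                                            "forward_euler", record_stride=100)
    c = snaps[:, rt.nc + rt.ng]
    # leak holds V ≈ −60 up to the small src perturbation; I_src ≈ g(V−E)
    V = snaps[:, 0]
    I_src = 0.01 * (V[-1] - 40.0)
    c_star = -0.5 * I_src
    exact = c_star * (1.0 - np.exp(-4.0 * times))
    assert np.max(np.abs(c - exact)) < 1e-4 * c_star + 1e-9


def test_regulation_factor_limits_and_monotonicity():
    act = RegulationLink("Ca", "saturating_activation", gamma=2.0)
    inh = RegulationLink("Ca", "inhibition", gamma=2.0)
    assert regulation_factor(0.0, act) == 0.0
    assert regulation_factor(0.0, inh) == 1.0
    assert regulation_factor(0.5, act) == pytest.approx(0.5)   # γc = 1
    assert regulation_factor(0.5, inh) == pytest.approx(0.5)
    c = np.linspace(0, 50, 1000)
    fa = np.array([regulation_factor(x, act) for x in c])
    fi = np.array([regulation_factor(x, inh) for x in c])
    assert np.all(np.diff(fa) > 0) and fa[-1] < 1.0
    assert np.all(np.diff(fi) < 0) and fi[-1] > 0.0


# ---------------------------------------------------------------------------
# electrical synapses
# ---------------------------------------------------------------------------

def test_electrical_current_values_and_antisymmetry(rng):
    syn = ElectricalSynapseSpec("a", "b", gbar=0.5)
    assert electrical_current(-50.0, -50.0, syn) == 0.0
    assert electrical_current(-40.0, -50.0, syn) == pytest.approx(5.0)
    for _ in range(100):
        vi, vj = rng.uniform(-90, 40, size=2)
        assert electrical_current(vi, vj, syn) == pytest.approx(
            -electrical_current(vj, vi, syn))
    rect = ElectricalSynapseSpec("a", "b", gbar=0.5, rectifying=True)
    assert electrical_current(-60.0, -50.0, rect) == 0.0
    assert electrical_current(-40.0, -50.0, rect) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# chemical synapses
# ---------------------------------------------------------------------------

def test_dual_exp_peak_normalisation():
    tr, td = 2e-3, 10e-3
    tp = dual_exp_peak_time(tr, td)
    assert tp == pytest.approx(tr * td / (td - tr) * math.log(td / tr))
    norm = dual_exp_norm(tr, td)
    peak = norm * (math.exp(-tp / td) - math.exp(-tp / tr))
    assert peak == pytest.approx(1.0)
    # single event peaks at exactly 1 at t = tp
    t = np.linspace(0, 0.06, 2000)
    Y = norm * (np.exp(-t / td) - np.exp(-t / tr))
    assert Y.max() == pytest.approx(1.0, abs=1e-5)
    assert abs(t[Y.argmax()] - tp) < 1e-4


def test_synapse_m1_composition():
    assert synapse_m1(0.0, 0.0, 3.0) == 0.0  # no events
    norm = dual_exp_norm(2e-3, 10e-3)
    val = synapse_m1(0.2, 0.7, norm, d=0.5, fac_gain=2.0)
    assert val == pytest.approx(norm * 0.5 * 0.5 * 2.0)


def test_event_driven_kernel_matches_convolution():
    """Event-driven accumulators equal the kernel convolution of the train."""
    tr, td = 2e-3, 10e-3
    norm = dual_exp_norm(tr, td)
    dt = 1e-4
    t = np.arange(0, 1.0 + dt / 2, dt)
    events = np.array([0.05, 0.12, 0.121, 0.3, 0.55, 0.555, 0.56, 0.9])
    events = np.round(events / dt) * dt  # place events on the grid
    # event-driven: exact decay between samples plus unit jumps
    yr = yd = 0.0
    Y_event = np.zeros_like(t)
    fr, fd = math.exp(-dt / tr), math.exp(-dt / td)
    for i in range(1, t.size):
        yr *= fr
        yd *= fd
        n = np.sum((events > t[i - 1] + 1e-12) & (events <= t[i] + 1e-12))
        yr += n
        yd += n
        Y_event[i] = norm * (yd - yr)
    # brute-force convolution oracle
    Y_conv = np.zeros_like(t)
    for e in events:
        tau_ = t - e
        mask = tau_ > 1e-12
        Y_conv[mask] += norm * (np.exp(-tau_[mask] / td)
                                - np.exp(-tau_[mask] / tr))
    rms = np.sqrt(np.mean((Y_event - Y_conv) ** 2))
    assert rms < 1e-8


def test_depression_map_and_fixed_point():
    assert depression_event_update(0.8, 0.0) == 0.8  # u = 0 is the identity
    d = 1.0
    for _ in range(2):
        d = depression_event_update(1.0, 0.3)  # full recovery between spikes
        assert d == pytest.approx(0.7)
    assert depression_derivative(1.0, 0.5) == 0.0
    assert depression_derivative(0.5, 0.5) == pytest.approx(1.0)
    # periodic train at interval Δ: pre-spike d converges to
    # d* = (1−e^(−Δ/τ)) / (1−(1−u)e^(−Δ/τ))
    u, tau_rec, delta = 0.25, 2.0, 0.07
    a = math.exp(-delta / tau_rec)
    d_star = (1 - a) / (1 - (1 - u) * a)
    d = 1.0
    for _ in range(500):
        d = 1.0 + (depression_event_update(d, u) - 1.0) * a
    assert d == pytest.approx(d_star, rel=1e-9)


@given(st.floats(0, 1), st.floats(0, 1))
def test_depression_stays_bounded(d, u):
    assert 0.0 <= depression_event_update(d, u) <= 1.0


def test_m2_derivative_forms():
    assert m2_derivative(0.37, -50.0, None) == 0.0  # no voltage dependence
    vd = VoltageDependence(h=-30.0, s=10.0, tau_m2=5e-3)
    assert m2_derivative(0.5, -30.0, vd) == pytest.approx(0.0)  # midpoint
    assert m2_derivative(0.2, -30.0, vd) == pytest.approx(0.3 / 5e-3)


def test_chemical_current_product_form():
    from cpgsim.schema_io import ChemicalSynapseSpec

    syn = ChemicalSynapseSpec("a", "b", w=1.0, E=0.0, tau_rise=2e-3,
                              tau_decay=1e-2)
    assert chemical_current(-50.0, syn, M1=0.0) == 0.0
    assert chemical_current(-20.0, syn, M1=0.5, M2=1.0) == pytest.approx(-10.0)
    assert chemical_current(0.0, syn, M1=0.5, M2=1.0) == 0.0


# ---------------------------------------------------------------------------
# assembled derivative
# ---------------------------------------------------------------------------

def test_rest_state_has_zero_derivatives():
    spec = make_fixture("leaky").spec
    rt = RuntimeNetwork(spec)
    stt = rt.initial_state()
    rt.stimuli_enabled = False
    dy = rt.derivative(0.0, stt)
    assert np.max(np.abs(dy)) == 0.0


def test_current_breakdown_identity_random_states(rng):
    """Cm·dV/dt = I_app − ΣI_vd − ΣI_es − ΣI_cs − I_noise to round-off."""
    spec = make_fixture("plastic_triad").spec
    rt = RuntimeNetwork(spec)
    for _ in range(100):
        stt = rt.initial_state()
        stt.V = rng.uniform(-80, 20, rt.nc)
        stt.gates = rng.uniform(0, 1, rt.ng)
        stt.pools = rng.uniform(0, 1, rt.npool)
        stt.syn_yr = rng.uniform(0, 2, rt.ns)
        stt.syn_yd = rng.uniform(0, 2, rt.ns)
        stt.syn_d = rng.uniform(0, 1, rt.ns)
        stt.t = rng.uniform(0, 4)
        derivs, bd = assemble_derivative(stt, spec)
        lhs = rt.Cm * derivs["V"]
        rhs = bd.I_app - bd.I_vd - bd.I_es - bd.I_cs - bd.I_noise
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


def test_gap_junction_conservation_and_symmetry():
    spec = make_fixture("gap_pair").spec
    rt = RuntimeNetwork(spec)
    rt.stimuli_enabled = False
    stt = rt.initial_state()
    stt.V = np.array([-40.0, -60.0])
    _, bd = assemble_derivative(stt, spec)
    assert bd.I_es[0] == pytest.approx(-bd.I_es[1])  # conservation
    # identical cells from symmetric states evolve identically
    stt.V = np.array([-55.0, -55.0])
    derivs, _ = assemble_derivative(stt, spec)
    assert derivs["V"][0] == pytest.approx(derivs["V"][1])


def test_dimension_mismatch_raises():
    spec = make_fixture("leaky").spec
    rt = RuntimeNetwork(spec)
    stt = rt.initial_state()
    stt.V = np.zeros(3)
    with pytest.raises(NetworkValueError, match="compartments"):
        assemble_derivative(stt, spec)
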