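"""Programmatic test networks and their analytic / brute-force oracles.

Every network used in the test suite is generated here, so the whole package
is testable without any external file:

* ``leaky`` — single leak-only cell with a current pulse; three-piece exact
  solution (:func:`leaky_exact`).
* ``spiker_capool`` — spiking cell whose Ca influx feeds a pool that both
  activates a K(Ca) conductance and feeds back onto the Ca channel,
  producing spike-rate attenuation during a 2 nA, 5 s pulse.
* ``gap_pair`` — two identical spiking cells coupled by a gap junction.
* ``plastic_triad`` — three spiking cells with facilitating inhibitory and
  depressing excitatory synapses.
* ``vdep_pair`` — spiker onto a passive cell through a voltage-dependent
  excitatory synapse; PSP amplitude is probed across holding potentials
  −90…−10 mV.
* ``burst_alternator`` — two-cell half-centre whose burst durations are set
  by K(Ca) adaptation; used by the sweep tests.
* ``tonic_spiker`` — spontaneously active cell (depolarised leak reversal)
  that never satisfies the relaxation criterion.

Channel kinetics are our own frozen constants chosen for robust spiking in
the closed µF/µS/mV/s/nA/mM unit system (membrane time constant 100 ms,
sodium activation 0.1 ms): they reproduce the mechanisms under test, not any
particular biological cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .events_noise import EventTrain
from .schema_io import (
    ChannelSpec,
    ChemicalSynapseSpec,
    CompartmentSpec,
    Depression,
    ElectricalSynapseSpec,
    Facilitation,
    GateSpec,
    IonPoolSpec,
    NetworkSpec,
    NetworkValueError,
    NeuronSpec,
    RegulationLink,
    SimulationConfig,
    StimulusSpec,
    VoltageDependence,
)

__all__ = [
    "FixtureProblem",
    "leaky_exact",
    "make_fixture",
    "get_problem",
    "synthetic_bursts",
    "solve_holding_current",
    "psp_amplitude_curve",
    "plasticity_pair",
    "psp_peaks",
    "FIXTURE_IDS",
]


# ---------------------------------------------------------------------------
# Analytic oracle for the leaky integrator
# ---------------------------------------------------------------------------

def leaky_exact(t, Cm: float, g_leak: float, V_leak: float,
                I0: float, t0: float, t1: float):
    """Exact membrane potential of a leak-only cell under a current pulse.

    Cm dV/dt = I_app − g_leak (V − V_leak) with I_app = I0 on [t0, t1),
    V(0) = V_leak; three-piece closed form with τ = Cm/g_leak.
    """
    if not t1 > t0 >= 0:
        raise NetworkValueError("pulse needs t1 > t0 >= 0")
    t = np.asarray(t, dtype=float)
    tau = Cm / g_leak
    dV = I0 / g_leak
    rise = V_leak + dV * (1.0 - np.exp(-(t - t0) / tau))
    peak = V_leak + dV * (1.0 - math.exp(-(t1 - t0) / tau))
    fall = V_leak + (peak - V_leak) * np.exp(-(t - t1) / tau)
    out = np.where(t < t0, V_leak, np.where(t < t1, rise, fall))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Building blocks (frozen fixture constants)
# ---------------------------------------------------------------------------

_CM = 0.005        # µF; with g_leak = 0.05 µS the membrane τ is 100 ms
_G_LEAK = 0.05     # µS
_E_LEAK = -60.0    # mV

def _na_channel(gbar: float = 15.0) -> ChannelSpec:
    return ChannelSpec(
        name="Na", gbar=gbar, E=55.0,
        activation=GateSpec(h=-40.0, s=4.0, tau=2e-4), p=3,
        inactivation=GateSpec(h=-45.0, s=-4.0, tau=1.5e-3), q=1)

def _k_channel(gbar: float = 5.0) -> ChannelSpec:
    return ChannelSpec(
        name="K", gbar=gbar, E=-75.0,
        activation=GateSpec(h=-25.0, s=5.0, tau=3e-3), p=1)

def _leak(g: float = _G_LEAK, E: float = _E_LEAK) -> ChannelSpec:
    return ChannelSpec(name="leak", gbar=g, E=E)


def _spiker(name: str, extra_channels=(), pools=(), V_init=-60.0,
            g_leak=_G_LEAK, E_leak=_E_LEAK, g_na=15.0, g_k=5.0) -> NeuronSpec:
    comp = CompartmentSpec(
        name="soma", Cm=_CM,
        channels=(_leak(g_leak, E_leak), _na_channel(g_na), _k_channel(g_k))
        + tuple(extra_channels),
        pools=tuple(pools), V_init=V_init)
    return NeuronSpec(name=name, compartments=(comp,))


def _ca_system(g_ca: float = 1.0, k1: float = 1.0, k2: float = 0.2,
               feedback_gamma: float = 1.0):
    """N-type-like Ca channel feeding a pool, with Ca negative feedback."""
    ca = ChannelSpec(
        name="CaN", gbar=g_ca, E=80.0,
        activation=GateSpec(h=-25.0, s=5.0, tau=1e-3), p=2,
        regulation=RegulationLink(pool="Ca", form="inhibition",
                                  gamma=feedback_gamma),
        feeds_pool="Ca")
    pool = IonPoolSpec(name="Ca", k1=k1, k2=k2,
                       source_channels=("CaN",), c_init=0.0)
    return ca, pool


# ---------------------------------------------------------------------------
# Fixture problems
# ---------------------------------------------------------------------------

@dataclass
class FixtureProblem:
    """A test network plus its reference protocol and (optional) oracle."""

    id: str
    spec: NetworkSpec
    exact: Callable | None = None   # exact V(t) of the first compartment
    V0: float = -60.0               # initial V used by convergence studies
    t_end: float = 1.0
    notes: str = ""


_LEAKY = dict(Cm=1.0, g_leak=0.1, V_leak=-60.0, I0=2.0, t0=2.0, t1=7.0)


def _leaky_problem() -> FixtureProblem:
    p = _LEAKY
    neuron = NeuronSpec(name="L", compartments=(CompartmentSpec(
        name="soma", Cm=p["Cm"],
        channels=(_leak(p["g_leak"], p["V_leak"]),), V_init=p["V_leak"]),))
    spec = NetworkSpec(
        neurons=(neuron,),
        stimuli=(StimulusSpec("L", "current_pulse", p["I0"], p["t0"], p["t1"]),),
        sim=SimulationConfig(duration=12.0, method="adaptive",
                             record=(("L", "V"),), record_dt=1e-2))
    return FixtureProblem(
        id="leaky", spec=spec,
        exact=lambda t: leaky_exact(t, p["Cm"], p["g_leak"], p["V_leak"],
                                    p["I0"], p["t0"], p["t1"]),
        V0=p["V_leak"], t_end=12.0,
        notes="leak-only cell, +2 nA pulse from 2 to 7 s; τ = 10 s")


def _smooth_decay_problem() -> FixtureProblem:
    # pure exponential decay toward 0 from +10 mV; k = g/Cm = 1 s⁻¹
    neuron = NeuronSpec(name="D", compartments=(CompartmentSpec(
        name="soma", Cm=1.0, channels=(_leak(1.0, 0.0),), V_init=10.0),))
    spec = NetworkSpec(
        neurons=(neuron,),
        sim=SimulationConfig(duration=2.0, method="adaptive",
                             record=(("D", "V"),)))
    return FixtureProblem(
        id="smooth_decay", spec=spec,
        exact=lambda t: 10.0 * np.exp(-np.asarray(t, dtype=float)),
        V0=10.0, t_end=2.0,
        notes="smooth linear decay dV/dt = −V; classical order oracle")


def _spiker_capool_problem() -> FixtureProblem:
    ca, pool = _ca_system(g_ca=1.0, k1=1.0, k2=0.2, feedback_gamma=1.0)
    kca = ChannelSpec(
        name="KCa", gbar=2.5, E=-75.0,
        activation=GateSpec(h=-30.0, s=6.0, tau=2e-3), p=1,
        regulation=RegulationLink(pool="Ca", form="saturating_activation",
                                  gamma=2.0))
    neuron = _spiker("B", extra_channels=(ca, kca), pools=(pool,))
    spec = NetworkSpec(
        neurons=(neuron,),
        stimuli=(StimulusSpec("B", "current_pulse", 2.0, 0.5, 5.5),),
        sim=SimulationConfig(duration=6.0, method="adaptive", abstol=1e-6,
                             reltol=1e-6, dt=2.5e-5,
                             record=(("B", "V"), ("B", "c_Ca"),
                                     ("B", "I_KCa"), ("B", "f_KCa")),
                             record_dt=2.5e-4))
    return FixtureProblem(
        id="spiker_capool", spec=spec, t_end=6.0,
        notes="2 nA, 5 s pulse; Ca pool activates K(Ca) → spike-rate attenuation")


def _gap_pair_problem() -> FixtureProblem:
    A = _spiker("A")
    B = _spiker("B")
    spec = NetworkSpec(
        neurons=(A, B),
        electrical_synapses=(ElectricalSynapseSpec("A", "B", 0.005),),
        stimuli=(StimulusSpec("A", "current_pulse", 2.0, 0.5, 2.5),),
        sim=SimulationConfig(duration=3.0, method="adaptive", abstol=1e-6,
                             reltol=1e-6, dt=2.5e-5,
                             record=(("A", "V"), ("B", "V")),
                             record_dt=2.5e-4))
    return FixtureProblem(
        id="gap_pair", spec=spec, t_end=6.0,
        notes="spikes in A produce same-sign subthreshold deflections in B")


def _plastic_triad_problem() -> FixtureProblem:
    pools = lambda: _ca_system(g_ca=0.5, k1=1.0, k2=0.2, feedback_gamma=0.0)
    caA, poolA = pools()
    caB, poolB = pools()
    caC, poolC = pools()
    A = _spiker("A", extra_channels=(caA,), pools=(poolA,))
    B = _spiker("B", extra_channels=(caB,), pools=(poolB,))
    C = _spiker("C", extra_channels=(caC,), pools=(poolC,))
    syns = (
        # facilitating inhibitory pair A<->B (different rates)
        ChemicalSynapseSpec("A", "B", w=0.02, E=-80.0, tau_rise=2e-3,
                            tau_decay=10e-3,
                            facilitation=Facilitation("Ca", 5.0)),
        ChemicalSynapseSpec("B", "A", w=0.02, E=-80.0, tau_rise=2e-3,
                            tau_decay=10e-3,
                            facilitation=Facilitation("Ca", 2.0)),
        # depressing excitatory A->C
        ChemicalSynapseSpec("A", "C", w=0.005, E=0.0, tau_rise=2e-3,
                            tau_decay=10e-3,
                            depression=Depression(u=0.25, tau_rec=2.0)),
        # facilitating + depressing excitatory C->A
        ChemicalSynapseSpec("C", "A", w=0.005, E=0.0, tau_rise=2e-3,
                            tau_decay=10e-3,
                            facilitation=Facilitation("Ca", 2.0),
                            depression=Depression(u=0.2, tau_rec=1.0)),
    )
    spec = NetworkSpec(
        neurons=(A, B, C), chemical_synapses=syns,
        stimuli=(StimulusSpec("A", "current_pulse", 2.0, 0.5, 3.5),),
        sim=SimulationConfig(duration=4.0, method="adaptive", abstol=1e-6,
                             reltol=1e-6, dt=2e-5,
                             record=(("A", "V"), ("B", "V"), ("C", "V"),
                                     ("A", "c_Ca")),
                             record_dt=2.5e-4))
    return FixtureProblem(
        id="plastic_triad", spec=spec, t_end=4.0,
        notes="driving A: facilitating IPSPs in B grow, depressing EPSPs in C shrink")


def plasticity_pair(kind: str) -> FixtureProblem:
    """Spiker driving a fast passive cell through one plastic synapse.

    ``kind``: ``depressing`` (u = 0.25, τ_rec = 2 s) or ``facilitating``
    (transmitter gain driven by the presynaptic Ca pool, γ_f = 5 mM⁻¹).
    The postsynaptic membrane time constant is 20 ms, well below the ~67 ms
    presynaptic ISI, so successive PSPs barely summate and their peak
    sequence tracks the plasticity variable directly.
    """
    if kind == "depressing":
        extra, pools = (), ()
        syn = ChemicalSynapseSpec(
            "A", "B", w=0.02, E=0.0, tau_rise=2e-3, tau_decay=10e-3,
            depression=Depression(u=0.25, tau_rec=2.0))
    elif kind == "facilitating":
        ca, pool = _ca_system(g_ca=0.5, k1=1.0, k2=0.2, feedback_gamma=0.0)
        extra, pools = (ca,), (pool,)
        syn = ChemicalSynapseSpec(
            "A", "B", w=0.02, E=0.0, tau_rise=2e-3, tau_decay=10e-3,
            facilitation=Facilitation("Ca", 5.0))
    else:
        raise NetworkValueError("kind must be 'depressing' or 'facilitating'")
    A = _spiker("A", extra_channels=extra, pools=pools)
    B = NeuronSpec(name="B", compartments=(CompartmentSpec(
        name="soma", Cm=_CM, channels=(_leak(0.25, _E_LEAK),),
        V_init=_E_LEAK),))
    record = [("A", "V"), ("B", "V")]
    if kind == "facilitating":
        record.append(("A", "c_Ca"))
    spec = NetworkSpec(
        neurons=(A, B), chemical_synapses=(syn,),
        stimuli=(StimulusSpec("A", "current_pulse", 2.0, 0.2, 2.2),),
        sim=SimulationConfig(duration=2.4, method="adaptive", abstol=1e-7,
                             reltol=1e-7, dt=2e-5, record=tuple(record),
                             record_dt=1e-4))
    return FixtureProblem(
        id=f"plasticity_pair_{kind}", spec=spec, t_end=2.4,
        notes="regular presynaptic train; PSP peak sequence tracks d or 1+γ_f·c")


def psp_peaks(traces, pre: str = "A", post: str = "B",
              window: float = 0.06) -> np.ndarray:
    """Per-presynaptic-spike PSP amplitudes, measured from each event's own
    pre-event baseline so temporal summation does not contaminate the
    sequence.  Positive for EPSPs and IPSPs alike (absolute deflection)."""
    from .events_noise import detect_spikes

    t = traces.time
    Vpre = traces.data[(pre, "V")]
    Vpost = traces.data[(post, "V")]
    spikes = detect_spikes(t, Vpre).times
    amps = []
    for k, s in enumerate(spikes):
        e = min(spikes[k + 1] if k + 1 < len(spikes) else s + window, s + window)
        base = Vpost[max(0, np.searchsorted(t, s) - 1)]
        sel = (t >= s) & (t < e)
        if not sel.any():
            continue
        up = Vpost[sel].max() - base
        dn = base - Vpost[sel].min()
        amps.append(up if up >= dn else dn)
    return np.array(amps)


def _vdep_pair_problem() -> FixtureProblem:
    # leak reversal −52 mV puts A ~90 ms from threshold under +1 nA, so the
    # 150 ms pulse reliably evokes a single spike
    A = _spiker("A", E_leak=-52.0, V_init=-52.0)
    B = NeuronSpec(name="B", compartments=(CompartmentSpec(
        name="soma", Cm=_CM, channels=(_leak(0.25, _E_LEAK),), V_init=_E_LEAK),))
    syn = ChemicalSynapseSpec(
        "A", "B", w=0.02, E=30.0, tau_rise=2e-3, tau_decay=10e-3,
        voltage_dependence=VoltageDependence(h=-10.0, s=12.0, tau_m2=2e-3))
    spec = NetworkSpec(
        neurons=(A, B), chemical_synapses=(syn,),
        stimuli=(StimulusSpec("A", "current_pulse", 1.0, 1.0, 1.15),),
        sim=SimulationConfig(duration=1.6, method="adaptive", abstol=1e-8,
                             reltol=1e-8, dt=2e-5,
                             record=(("A", "V"), ("B", "V")),
                             record_dt=1e-4))
    return FixtureProblem(
        id="vdep_pair", spec=spec, t_end=1.6,
        notes="+1 nA, 150 ms pulse to A; B held at −90…−10 mV by holding current")


def _burst_alternator_problem() -> FixtureProblem:
    def cell(name, V_init):
        ca, pool = _ca_system(g_ca=1.0, k1=0.7, k2=0.3, feedback_gamma=0.0)
        kca = ChannelSpec(
            name="KCa", gbar=3.0, E=-75.0,
            activation=GateSpec(h=-30.0, s=6.0, tau=5e-3), p=1,
            regulation=RegulationLink(pool="Ca", form="saturating_activation",
                                      gamma=3.0))
        return _spiker(name, extra_channels=(ca, kca), pools=(pool,),
                       V_init=V_init)
    X, Y = cell("X", -50.0), cell("Y", -70.0)
    syns = (
        ChemicalSynapseSpec("X", "Y", w=0.15, E=-80.0, tau_rise=2e-3,
                            tau_decay=50e-3),
        ChemicalSynapseSpec("Y", "X", w=0.15, E=-80.0, tau_rise=2e-3,
                            tau_decay=50e-3),
    )
    spec = NetworkSpec(
        neurons=(X, Y), chemical_synapses=syns,
        stimuli=(StimulusSpec("X", "holding_current", 2.0),
                 StimulusSpec("Y", "holding_current", 2.0)),
        sim=SimulationConfig(duration=12.0, method="adaptive", abstol=1e-6,
                             reltol=1e-6, dt=2e-5, relax_max=0.2,
                             record=(("X", "V"), ("Y", "V")),
                             record_dt=2.5e-4))
    return FixtureProblem(
        id="burst_alternator", spec=spec, t_end=12.0,
        notes="half-centre: mutual inhibition + K(Ca) adaptation → alternating bursts")


def _tonic_spiker_problem() -> FixtureProblem:
    neuron = _spiker("T", E_leak=-40.0, V_init=-50.0)
    spec = NetworkSpec(
        neurons=(neuron,),
        sim=SimulationConfig(duration=2.0, method="forward_euler", dt=2e-5,
                             relax_max=0.5, record=(("T", "V"),),
                             record_dt=2.5e-4))
    return FixtureProblem(
        id="tonic_spiker", spec=spec, t_end=2.0,
        notes="depolarised leak reversal: fires without stimulus, never relaxes")


_BUILDERS = {
    "leaky": _leaky_problem,
    "smooth_decay": _smooth_decay_problem,
    "spiker_capool": _spiker_capool_problem,
    "gap_pair": _gap_pair_problem,
    "plastic_triad": _plastic_triad_problem,
    "vdep_pair": _vdep_pair_problem,
    "burst_alternator": _burst_alternator_problem,
    "tonic_spiker": _tonic_spiker_problem,
}

FIXTURE_IDS = tuple(sorted(_BUILDERS))


def make_fixture(id: str) -> FixtureProblem:
    """Build a fixture network and protocol by id."""
    try:
        builder = _BUILDERS[id]
    except KeyError:
        raise NetworkValueError(
            f"unknown fixture '{id}'; known ids: {', '.join(FIXTURE_IDS)}") from None
    return builder()


def get_problem(id: str) -> FixtureProblem:
    """Fixture with a registered exact solution (for convergence studies)."""
    prob = make_fixture(id)
    if prob.exact is None:
        raise NetworkValueError(f"fixture '{id}' has no exact solution")
    return prob


# ---------------------------------------------------------------------------
# Synthetic burst trains (ground truth for the phase analysis)
# ---------------------------------------------------------------------------

def synthetic_bursts(protraction: float, retraction: float, n_patterns: int,
                     isi: float = 0.05, jitter_sd: float = 0.0,
                     seed: int = 0, gap: float = 1.0):
    """Alternating protraction/retraction spike bursts with known durations.

    Each pattern is a protraction burst (duration ``protraction`` s, spikes
    ``isi`` apart) followed after ``gap`` s by a retraction burst; durations
    are jittered by N(0, jitter_sd²), truncated positive.  Returns the two
    event trains.
    """
    if protraction <= 0 or retraction <= 0:
        raise NetworkValueError("durations must be > 0")
    rng = np.random.default_rng(seed)
    t = 0.0
    pro, ret = [], []
    for _ in range(n_patterns):
        dp = max(2 * isi, protraction + (rng.normal(0, jitter_sd) if jitter_sd else 0.0))
        dr = max(2 * isi, retraction + (rng.normal(0, jitter_sd) if jitter_sd else 0.0))
        n = int(round(dp / isi))
        pro.append(t + np.arange(n + 1) * (dp / n))
        t += dp + gap
        n = int(round(dr / isi))
        ret.append(t + np.arange(n + 1) * (dr / n))
        t += dr + gap
    return (EventTrain("protraction", np.concatenate(pro), "spike"),
            EventTrain("retraction", np.concatenate(ret), "spike"))


# ---------------------------------------------------------------------------
# Holding-current solver and PSP amplitude curve
# ---------------------------------------------------------------------------

def solve_holding_current(spec: NetworkSpec, comp: str, target_V: float,
                          I_range: tuple[float, float] = (-25.0, 25.0),
                          settle: float = 1.5, tol: float = 1e-6) -> float:
    """Holding current (nA) whose noiseless steady state puts ``comp`` at
    ``target_V``, found by root bracketing on the settled potential."""
    from .dynamics import RuntimeNetwork
    from .integrators import integrate_adaptive, relax

    base = replace(spec, stimuli=(), noise=())

    def settled_V(I: float) -> float:
        s = replace(base, stimuli=(StimulusSpec(comp, "holding_current", I),))
        rt = RuntimeNetwork(s)
        st = rt.initial_state()
        st, _ = relax(rt, st, relax_max=0.5, dvdt_tol=5e-2)
        st, *_ = integrate_adaptive(rt, st, settle, 1e-8, 1e-8)
        return float(st.V[rt.resolve(comp)])

    f = lambda I: settled_V(I) - target_V
    lo, hi = I_range
    return float(brentq(f, lo, hi, xtol=tol))


def psp_amplitude_curve(holds=None, fixture: FixtureProblem | None = None,
                        post: str = "B", window: tuple[float, float] = (1.0, 1.4)):
    """Peak PSP amplitude in the ``vdep_pair`` fixture across holding
    potentials (mV).  Returns ``(holds, amplitudes)`` arrays.

    For each holding potential the holding current is solved so the settled
    postsynaptic potential equals it, a single presynaptic spike is evoked,
    and the amplitude is max(V_post) − V_hold over the response window.
    """
    from .runner import run_simulation

    prob = fixture or make_fixture("vdep_pair")
    if holds is None:
        holds = np.arange(-90.0, -9.0, 10.0)
    holds = np.asarray(holds, dtype=float)
    amps = []
    for Vh in holds:
        I = solve_holding_current(prob.spec, post, Vh)
        stim = tuple(prob.spec.stimuli) + (
            StimulusSpec(post, "holding_current", I),)
        spec = replace(prob.spec, stimuli=stim)
        traces, _ = run_simulation(spec)
        t = traces.time
        V = traces.data[(post, "V")]
        sel = (t >= window[0]) & (t <= window[1])
        base = V[(t >= window[0] - 0.05) & (t < window[0])].mean()
        amps.append(float(V[sel].max() - base))
    return holds, np.array(amps)
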