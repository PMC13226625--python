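"""Right-hand side of the network ODE system.

The membrane balance for compartment i is

    Cm dVi/dt = I_app − ΣI(vd) − ΣI(es) − ΣI(cs) − I(noise)

with voltage-dependent channel currents I(vd) = ḡ·A^p·B^q·(V−E)·f[reg],
resistive coupling I(es) = ḡ·(Vi−Vj), chemical synapses
I(cs) = ḡ·M1(t)·M2(t,V)·(V−E), and the balanced background conductances of
:mod:`cpgsim.events_noise`.  Gates relax first order toward sigmoid steady
states; ion pools integrate their source-channel currents; M1 is a
peak-normalised dual-exponential accumulated over presynaptic events and
multiplied by the plasticity gain X = (1 + γ_f·c_pre)·d.

The module exposes both scalar primitives (unit-testable closed forms) and a
compiled :class:`RuntimeNetwork` that evaluates the full vectorised RHS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schema_io import (
    ChannelSpec,
    ChemicalSynapseSpec,
    ElectricalSynapseSpec,
    GateSpec,
    IonPoolSpec,
    NetworkSpec,
    NetworkValueError,
    RegulationLink,
    validate_network,
)

__all__ = [
    "gate_inf",
    "gate_tau",
    "gate_derivative",
    "channel_current",
    "pool_derivative",
    "regulation_factor",
    "electrical_current",
    "dual_exp_peak_time",
    "dual_exp_norm",
    "synapse_m1",
    "depression_event_update",
    "depression_derivative",
    "m2_derivative",
    "chemical_current",
    "NetworkState",
    "CurrentBreakdown",
    "RuntimeNetwork",
    "assemble_derivative",
]


# ---------------------------------------------------------------------------
# Scalar primitives
# ---------------------------------------------------------------------------

def gate_inf(V, h, s):
    """Sigmoid steady state 1/(1+exp((h−V)/s)); s < 0 gives a falling gate."""
    if np.any(np.asarray(s) == 0):
        raise NetworkValueError("slope factor s must be nonzero")
    return 1.0 / (1.0 + np.exp((h - V) / s))


def gate_tau(V, gate: GateSpec):
    """Gate time constant at voltage V (constant or sigmoid-of-V form), s."""
    if gate.voltage_dependent_tau:
        return gate.tau_base + gate.tau_amp / (
            1.0 + np.exp((gate.tau_h - V) / gate.tau_s))
    return gate.tau


def gate_derivative(A, V, gate: GateSpec):
    """First-order relaxation dA/dt = (A∞(V) − A)/τ(V), s⁻¹."""
    return (gate_inf(V, gate.h, gate.s) - A) / gate_tau(V, gate)


def channel_current(V, ch: ChannelSpec, A=1.0, B=1.0, f_reg=1.0):
    """ḡ·A^p·B^q·(V−E)·f_reg in nA."""
    gate = A ** ch.p if ch.p else 1.0
    if ch.q:
        gate = gate * B
    return ch.gbar * gate * (V - ch.E) * f_reg


def pool_derivative(c, I_src, pool: IonPoolSpec):
    """dc/dt = k1·(−k2·I_src − c): inward (negative) current accumulates."""
    return pool.k1 * (-pool.k2 * I_src - c)


def regulation_factor(c, link: RegulationLink):
    """f[reg] for a pool concentration c >= 0."""
    x = link.gamma * c
    if link.form == "saturating_activation":
        return x / (1.0 + x)
    if link.form == "inhibition":
        return 1.0 / (1.0 + x)
    raise NetworkValueError(f"unknown regulation form '{link.form}'")


def electrical_current(V_i, V_j, syn: ElectricalSynapseSpec):
    """Gap-junction current into cell i, nA; zero when rectifying and Vi<Vj."""
    I = syn.gbar * (V_i - V_j)
    if syn.rectifying:
        I = np.where(V_i > V_j, I, 0.0)
        if np.ndim(I) == 0:
            I = float(I)
    return I


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time after an event at which the dual-exponential kernel peaks."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Scale factor making a single event's kernel peak at exactly 1."""
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def synapse_m1(y_rise, y_decay, norm, d=1.0, fac_gain=1.0):
    """M1 = Y·X with Y = norm·(y_decay − y_rise) and X = fac_gain·d.

    ``y_rise``/``y_decay`` are the two exponential accumulators (each bumped
    by 1 per presynaptic event, decaying with τ_rise/τ_decay); ``fac_gain``
    is 1 + γ_f·c_pre.
    """
    Y = norm * (y_decay - y_rise)
    return Y * fac_gain * d


def depression_event_update(d, u):
    """Per-spike resource consumption d ← d·(1−u)."""
    return d * (1.0 - u)


def depression_derivative(d, tau_rec):
    """Recovery between spikes, dd/dt = (1−d)/τ_rec."""
    return (1.0 - d) / tau_rec


def m2_derivative(M2, V_post, vd):
    """First-order relaxation of the voltage-dependence factor; ``vd`` is a
    :class:`~cpgsim.schema_io.VoltageDependence` or None (M2 pinned at 1)."""
    if vd is None:
        return 0.0
    return (gate_inf(V_post, vd.h, vd.s) - M2) / vd.tau_m2


def chemical_current(V_post, syn: ChemicalSynapseSpec, M1, M2=1.0):
    """ḡ·M1·M2·(V_post−E) in nA."""
    return syn.w * M1 * M2 * (V_post - syn.E)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """All dynamical variables of a network at one instant.

    Smooth variables (V, gates, pools, M2) are advanced by the integrator;
    the event-driven linear variables (synapse kinetic pair, depression
    resource, noise conductances) decay exponentially between events and jump
    at events.
    """

    t: float
    V: np.ndarray           # mV, per compartment
    gates: np.ndarray       # in [0,1], per gate
    pools: np.ndarray       # mM, per pool
    syn_m2: np.ndarray      # in [0,1], per chemical synapse
    syn_yr: np.ndarray      # rise accumulator, per chemical synapse
    syn_yd: np.ndarray      # decay accumulator
    syn_d: np.ndarray       # depression resource, in [0,1]
    noise_gi: np.ndarray    # µS, per noise target
    noise_ge: np.ndarray    # µS

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.t, self.V.copy(), self.gates.copy(), self.pools.copy(),
            self.syn_m2.copy(), self.syn_yr.copy(), self.syn_yd.copy(),
            self.syn_d.copy(), self.noise_gi.copy(), self.noise_ge.copy())


@dataclass
class CurrentBreakdown:
    """Per-compartment split of the membrane balance, nA.

    Satisfies Cm·dV/dt = I_app − I_vd − I_es − I_cs − I_noise to round-off.
    """

    I_app: np.ndarray
    I_vd: np.ndarray
    I_es: np.ndarray
    I_cs: np.ndarray
    I_noise: np.ndarray


# ---------------------------------------------------------------------------
# Compiled runtime network
# ---------------------------------------------------------------------------

_REG_NONE, _REG_ACT, _REG_INH = 0, 1, 2


class RuntimeNetwork:
    """Index-array compilation of a :class:`NetworkSpec` for fast evaluation."""

    def __init__(self, spec: NetworkSpec):
        validate_network(spec)
        self.spec = spec
        self.comp_ids = spec.compartment_ids()
        self.nc = len(self.comp_ids)
        cindex = {cid: i for i, cid in enumerate(self.comp_ids)}

        def resolve(cid: str) -> int:
            # accept bare neuron names for single-compartment neurons and
            # fully qualified ids alike
            if cid in cindex:
                return cindex[cid]
            spec.compartment(cid)  # raises a diagnostic if truly unknown
            if "." not in cid:
                n = next(n for n in spec.neurons if n.name == cid)
                return cindex[f"{cid}.{n.compartments[0].name}"]
            return cindex[cid.split(".", 1)[0]]

        self.resolve = resolve

        Cm, V_init = [], []
        ch_comp, ch_gbar, ch_E, ch_p, ch_q = [], [], [], [], []
        ch_act, ch_inact = [], []
        ch_reg_pool, ch_reg_form, ch_reg_gamma = [], [], []
        gates: list[GateSpec] = []
        g_comp = []
        pools: list[IonPoolSpec] = []
        p_comp = []
        pool_key = {}
        chan_key = {}
        self.channel_names: list[tuple[str, str]] = []
        self.pool_names: list[tuple[str, str]] = []

        comp_list = []
        for n in spec.neurons:
            for c in n.compartments:
                cid = n.name if len(n.compartments) == 1 else f"{n.name}.{c.name}"
                comp_list.append((cid, c))
        for ci, (cid, c) in enumerate(comp_list):
            Cm.append(c.Cm)
            V_init.append(c.V_init)
            for p in c.pools:
                pool_key[(cid, p.name)] = len(pools)
                self.pool_names.append((cid, p.name))
                pools.append(p)
                p_comp.append(ci)
            for ch in c.channels:
                chan_key[(cid, ch.name)] = len(ch_comp)
                self.channel_names.append((cid, ch.name))
                ch_comp.append(ci)
                ch_gbar.append(ch.gbar)
                ch_E.append(ch.E)
                ch_p.append(float(ch.p))
                ch_q.append(float(ch.q))
                if ch.activation is not None:
                    ch_act.append(len(gates))
                    gates.append(ch.activation)
                    g_comp.append(ci)
                else:
                    ch_act.append(-1)
                if ch.inactivation is not None:
                    ch_inact.append(len(gates))
                    gates.append(ch.inactivation)
                    g_comp.append(ci)
                else:
                    ch_inact.append(-1)
                if ch.regulation is not None:
                    ch_reg_pool.append(pool_key[(cid, ch.regulation.pool)])
                    ch_reg_form.append(
                        _REG_ACT if ch.regulation.form == "saturating_activation"
                        else _REG_INH)
                    ch_reg_gamma.append(ch.regulation.gamma)
                else:
                    ch_reg_pool.append(-1)
                    ch_reg_form.append(_REG_NONE)
                    ch_reg_gamma.append(0.0)

        self.Cm = np.array(Cm)
        self._V_init = V_init
        self.nch = len(ch_comp)
        self.ch_comp = np.array(ch_comp, dtype=int)
        self.ch_gbar = np.array(ch_gbar)
        self.ch_E = np.array(ch_E)
        self.ch_p = np.array(ch_p)
        self.ch_q = np.array(ch_q)
        self.ch_act = np.array(ch_act, dtype=int)
        self.ch_inact = np.array(ch_inact, dtype=int)
        self.ch_reg_pool = np.array(ch_reg_pool, dtype=int)
        self.ch_reg_form = np.array(ch_reg_form, dtype=int)
        self.ch_reg_gamma = np.array(ch_reg_gamma)

        self.gates = gates
        self.ng = len(gates)
        self.g_comp = np.array(g_comp, dtype=int)
        self.g_h = np.array([g.h for g in gates])
        self.g_s = np.array([g.s for g in gates])
        self.g_tau_const = np.array(
            [g.tau if not g.voltage_dependent_tau else np.nan for g in gates])
        self.g_tau_vd = np.array([g.voltage_dependent_tau for g in gates], dtype=bool)
        self.g_tau_base = np.array(
            [g.tau_base if g.voltage_dependent_tau else 0.0 for g in gates])
        self.g_tau_amp = np.array(
            [g.tau_amp if g.voltage_dependent_tau else 0.0 for g in gates])
        self.g_tau_h = np.array(
            [g.tau_h if g.voltage_dependent_tau else 0.0 for g in gates])
        self.g_tau_s = np.array(
            [g.tau_s if g.voltage_dependent_tau else 1.0 for g in gates])
        self._any_gtau_vd = bool(self.g_tau_vd.any())

        self.pools = pools
        self.npool = len(pools)
        self.p_comp = np.array(p_comp, dtype=int)
        self.p_k1 = np.array([p.k1 for p in pools])
        self.p_k2 = np.array([p.k2 for p in pools])
        self.p_cinit = np.array([p.c_init for p in pools])
        src = np.zeros((self.npool, self.nch))
        for (cid, pname), pi in pool_key.items():
            for chname in pools[pi].source_channels:
                src[pi, chan_key[(cid, chname)]] = 1.0
        self.pool_src = src

        # electrical coupling: explicit synapses plus intra-neuron coupling
        e_i, e_j, e_g, e_rect = [], [], [], []
        for n in spec.neurons:
            prefix = n.name + "."
            for a, b, g in n.coupling:
                a = a if "." in a else prefix + a
                b = b if "." in b else prefix + b
                e_i.append(resolve(a))
                e_j.append(resolve(b))
                e_g.append(g)
                e_rect.append(False)
        for es in spec.electrical_synapses:
            e_i.append(resolve(es.cell_i))
            e_j.append(resolve(es.cell_j))
            e_g.append(es.gbar)
            e_rect.append(es.rectifying)
        self.ne = len(e_i)
        self.e_i = np.array(e_i, dtype=int)
        self.e_j = np.array(e_j, dtype=int)
        self.e_g = np.array(e_g)
        self.e_rect = np.array(e_rect, dtype=bool)

        # chemical synapses
        syns = spec.chemical_synapses
        self.ns = len(syns)
        self.syns = syns
        self.s_pre = np.array([resolve(s.pre) for s in syns], dtype=int)
        self.s_post = np.array([resolve(s.post) for s in syns], dtype=int)
        self.s_w = np.array([s.w for s in syns])
        self.s_E = np.array([s.E for s in syns])
        self.s_taur = np.array([s.tau_rise for s in syns])
        self.s_taud = np.array([s.tau_decay for s in syns])
        self.s_thr = np.array([s.threshold for s in syns])
        self.s_norm = np.array(
            [dual_exp_norm(s.tau_rise, s.tau_decay) for s in syns])
        self.s_fac_pool = np.array(
            [pool_key[(self.comp_ids[resolve(s.pre)], s.facilitation.pool)]
             if s.facilitation is not None else -1 for s in syns], dtype=int)
        self.s_fac_gamma = np.array(
            [s.facilitation.gamma_f if s.facilitation is not None else 0.0
             for s in syns])
        self.s_dep = np.array([s.depression is not None for s in syns], dtype=bool)
        self.s_u = np.array(
            [s.depression.u if s.depression is not None else 0.0 for s in syns])
        self.s_taurec = np.array(
            [s.depression.tau_rec if s.depression is not None else 1.0 for s in syns])
        self.s_vd = np.array(
            [s.voltage_dependence is not None for s in syns], dtype=bool)
        self.s_vd_h = np.array(
            [s.voltage_dependence.h if s.voltage_dependence is not None else 0.0
             for s in syns])
        self.s_vd_s = np.array(
            [s.voltage_dependence.s if s.voltage_dependence is not None else 1.0
             for s in syns])
        self.s_vd_tau = np.array(
            [s.voltage_dependence.tau_m2 if s.voltage_dependence is not None else 1.0
             for s in syns])
        self._any_vd = bool(self.s_vd.any())

        # noise targets
        self.nnz = len(spec.noise)
        self.nz_comp = np.array([resolve(nt.target) for nt in spec.noise], dtype=int)
        self.nz_taui = np.array([nt.tau_i for nt in spec.noise])
        self.nz_taue = np.array([nt.tau_e for nt in spec.noise])
        self.nz_Ei = np.array([nt.E_i for nt in spec.noise])
        self.nz_Ee = np.array([nt.E_e for nt in spec.noise])
        self.nz_wi = np.array([nt.w_i for nt in spec.noise])
        self.nz_we = np.zeros(self.nnz)  # derived at run time (balance rule)

        # stimuli
        self.nst = len(spec.stimuli)
        self.st_comp = np.array([resolve(s.target) for s in spec.stimuli], dtype=int)
        self.st_amp = np.array([s.amplitude for s in spec.stimuli])
        self.st_t0 = np.array(
            [s.t_start if s.kind == "current_pulse" else -np.inf for s in spec.stimuli])
        self.st_t1 = np.array(
            [s.t_end if s.kind == "current_pulse" else np.inf for s in spec.stimuli])

        # unique presynaptic (compartment, threshold) trigger groups
        trig = {}
        for si in range(self.ns):
            trig.setdefault((int(self.s_pre[si]), float(self.s_thr[si])), []).append(si)
        self.trigger_groups = [
            (comp, thr, np.array(sis, dtype=int)) for (comp, thr), sis in trig.items()]

        self.stimuli_enabled = True

    # -- state ------------------------------------------------------------
    def initial_state(self, default_V: float = -60.0) -> NetworkState:
        V = np.array([v if v is not None else default_V for v in self._V_init],
                     dtype=float)
        gates = np.array([gate_inf(V[self.g_comp[i]], g.h, g.s)
                          for i, g in enumerate(self.gates)], dtype=float) \
            if self.ng else np.zeros(0)
        return NetworkState(
            t=0.0, V=V, gates=gates, pools=self.p_cinit.copy(),
            syn_m2=np.where(self.s_vd, 0.0, 1.0) if self.ns else np.zeros(0),
            syn_yr=np.zeros(self.ns), syn_yd=np.zeros(self.ns),
            syn_d=np.ones(self.ns),
            noise_gi=np.zeros(self.nnz), noise_ge=np.zeros(self.nnz))

    # -- packing (smooth subvector advanced by the integrators) -----------
    def pack_smooth(self, st: NetworkState) -> np.ndarray:
        return np.concatenate([st.V, st.gates, st.pools, st.syn_m2])

    def unpack_smooth(self, y: np.ndarray, st: NetworkState) -> None:
        nc, ng, npo = self.nc, self.ng, self.npool
        st.V = y[:nc]
        st.gates = y[nc:nc + ng]
        st.pools = y[nc + ng:nc + ng + npo]
        st.syn_m2 = y[nc + ng + npo:]

    # -- pieces ------------------------------------------------------------
    def applied_current(self, t: float) -> np.ndarray:
        if self.nst and self.stimuli_enabled:
            on = (t >= self.st_t0) & (t < self.st_t1)
            return np.bincount(self.st_comp, weights=self.st_amp * on,
                               minlength=self.nc)
        return np.zeros(self.nc)

    def channel_currents(self, V, gates, pools):
        """Per-channel currents and the per-channel regulation factors."""
        gatef = np.ones(self.nch)
        if self.ng:
            act = self.ch_act >= 0
            gatef[act] = gates[self.ch_act[act]] ** self.ch_p[act]
            inact = self.ch_inact >= 0
            gatef[inact] *= gates[self.ch_inact[inact]]
        freg = np.ones(self.nch)
        act_reg = self.ch_reg_form == _REG_ACT
        inh_reg = self.ch_reg_form == _REG_INH
        if act_reg.any():
            x = self.ch_reg_gamma[act_reg] * pools[self.ch_reg_pool[act_reg]]
            freg[act_reg] = x / (1.0 + x)
        if inh_reg.any():
            x = self.ch_reg_gamma[inh_reg] * pools[self.ch_reg_pool[inh_reg]]
            freg[inh_reg] = 1.0 / (1.0 + x)
        Ich = self.ch_gbar * gatef * (V[self.ch_comp] - self.ch_E) * freg
        return Ich, freg

    def synapse_m1_values(self, st: NetworkState) -> np.ndarray:
        if not self.ns:
            return np.zeros(0)
        Y = self.s_norm * (st.syn_yd - st.syn_yr)
        gain = np.ones(self.ns)
        fac = self.s_fac_pool >= 0
        if fac.any():
            gain[fac] = 1.0 + self.s_fac_gamma[fac] * st.pools[self.s_fac_pool[fac]]
        return Y * gain * st.syn_d

    # -- full derivative ---------------------------------------------------
    def derivative(self, t: float, st: NetworkState,
                   with_breakdown: bool = False):
        """Time derivatives of the smooth variables; optionally the
        per-compartment current breakdown."""
        V, gates, pools = st.V, st.gates, st.pools

        Ich, _ = self.channel_currents(V, gates, pools)
        I_vd = np.bincount(self.ch_comp, weights=Ich, minlength=self.nc) \
            if self.nch else np.zeros(self.nc)

        if self.ng:
            Vg = V[self.g_comp]
            ginf = 1.0 / (1.0 + np.exp((self.g_h - Vg) / self.g_s))
            if self._any_gtau_vd:
                tau = np.where(
                    self.g_tau_vd,
                    self.g_tau_base + self.g_tau_amp
                    / (1.0 + np.exp((self.g_tau_h - Vg) / self.g_tau_s)),
                    self.g_tau_const)
            else:
                tau = self.g_tau_const
            dgates = (ginf - gates) / tau
        else:
            dgates = np.zeros(0)

        if self.npool:
            Isrc = self.pool_src @ Ich if self.nch else np.zeros(self.npool)
            dpools = self.p_k1 * (-self.p_k2 * Isrc - pools)
        else:
            dpools = np.zeros(0)

        if self.ne:
            dv = V[self.e_i] - V[self.e_j]
            Ie = self.e_g * dv
            if self.e_rect.any():
                Ie = np.where(self.e_rect & (dv <= 0), 0.0, Ie)
            I_es = (np.bincount(self.e_i, weights=Ie, minlength=self.nc)
                    - np.bincount(self.e_j, weights=Ie, minlength=self.nc))
        else:
            I_es = np.zeros(self.nc)

        if self.ns:
            M1 = self.synapse_m1_values(st)
            Isyn = self.s_w * M1 * st.syn_m2 * (V[self.s_post] - self.s_E)
            I_cs = np.bincount(self.s_post, weights=Isyn, minlength=self.nc)
            dm2 = np.zeros(self.ns)
            if self._any_vd:
                vd = self.s_vd
                m2inf = 1.0 / (1.0 + np.exp(
                    (self.s_vd_h[vd] - V[self.s_post[vd]]) / self.s_vd_s[vd]))
                dm2[vd] = (m2inf - st.syn_m2[vd]) / self.s_vd_tau[vd]
        else:
            I_cs = np.zeros(self.nc)
            dm2 = np.zeros(0)

        if self.nnz:
            Inz = (st.noise_gi * (V[self.nz_comp] - self.nz_Ei)
                   + st.noise_ge * (V[self.nz_comp] - self.nz_Ee))
            I_noise = np.bincount(self.nz_comp, weights=Inz, minlength=self.nc)
        else:
            I_noise = np.zeros(self.nc)

        I_app = self.applied_current(t)
        dV = (I_app - I_vd - I_es - I_cs - I_noise) / self.Cm
        dy = np.concatenate([dV, dgates, dpools, dm2])
        if with_breakdown:
            return dy, CurrentBreakdown(I_app, I_vd, I_es, I_cs, I_noise)
        return dy

    def _decay_factors(self, dt: float):
        cache = getattr(self, "_decay_cache", None)
        if cache is None:
            cache = self._decay_cache = {}
        f = cache.get(dt)
        if f is None:
            f = (np.exp(-dt / self.s_taur), np.exp(-dt / self.s_taud),
                 np.exp(-dt / self.s_taurec),
                 np.exp(-dt / self.nz_taui), np.exp(-dt / self.nz_taue))
            if len(cache) < 64:
                cache[dt] = f
        return f

    def decay_events(self, st: NetworkState, dt: float) -> None:
        """Exact exponential decay of the event-driven variables over dt."""
        fr, fd, frec, fgi, fge = self._decay_factors(dt)
        if self.ns:
            st.syn_yr *= fr
            st.syn_yd *= fd
            dep = self.s_dep
            if dep.any():
                st.syn_d[dep] = 1.0 + (st.syn_d[dep] - 1.0) * frec[dep]
        if self.nnz:
            st.noise_gi *= fgi
            st.noise_ge *= fge

    def apply_spikes(self, st: NetworkState, syn_indices: np.ndarray) -> None:
        """Presynaptic event: bump the kernel accumulators, consume resource."""
        st.syn_yr[syn_indices] += 1.0
        st.syn_yd[syn_indices] += 1.0
        st.syn_d[syn_indices] *= (1.0 - self.s_u[syn_indices])

    def clamp(self, st: NetworkState, track: bool = False) -> float:
        """Clamp bounded states into range; with ``track`` returns the
        largest excursion before clamping (bound-invariant audits)."""
        worst = 0.0
        if self.ng:
            if track:
                worst = max(worst, float(np.max(-st.gates, initial=0.0)),
                            float(np.max(st.gates - 1.0, initial=0.0)))
            np.clip(st.gates, 0.0, 1.0, out=st.gates)
        if self.npool:
            if track:
                worst = max(worst, float(np.max(-st.pools, initial=0.0)))
            np.clip(st.pools, 0.0, None, out=st.pools)
        if self.ns:
            if track:
                worst = max(worst, float(np.max(-st.syn_m2, initial=0.0)),
                            float(np.max(st.syn_m2 - 1.0, initial=0.0)))
            np.clip(st.syn_m2, 0.0, 1.0, out=st.syn_m2)
            np.clip(st.syn_d, 0.0, 1.0, out=st.syn_d)
        return worst


def assemble_derivative(state: NetworkState, spec: NetworkSpec):
    """Evaluate the full RHS for ``state`` under ``spec``.

    Returns ``(derivatives, breakdown)`` where ``derivatives`` maps the smooth
    variables (V, gates, pools, M2) to their time derivatives and
    ``breakdown`` is the per-compartment :class:`CurrentBreakdown`.
    """
    rt = RuntimeNetwork(spec)
    if state.V.shape != (rt.nc,):
        raise NetworkValueError(
            f"state has {state.V.shape[0]} compartments, spec has {rt.nc}")
    if state.gates.shape != (rt.ng,) or state.pools.shape != (rt.npool,):
        raise NetworkValueError("state dimensions do not match spec")
    dy, breakdown = rt.derivative(state.t, state, with_breakdown=True)
    nc, ng, npo = rt.nc, rt.ng, rt.npool
    derivs = {
        "V": dy[:nc],
        "gates": dy[nc:nc + ng],
        "pools": dy[nc + ng:nc + ng + npo],
        "syn_m2": dy[nc + ng + npo:],
    }
    return derivs, breakdown
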