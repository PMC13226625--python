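"""Workbook-based network description: typed spec, validation, xlsx I/O.

A network is described by a spreadsheet workbook with one sheet per entity
kind (``Neurons``, ``Channels``, ``Pools``, ``ElectricalSynapses``,
``ChemicalSynapses``, ``Noise``, ``Stimuli``, ``Simulation``).  The loader
parses the workbook into an immutable :class:`NetworkSpec`, applies defaults,
and cross-validates every reference; the writer emits a workbook that parses
back to an equal spec (canonical row ordering: neurons alphabetical, channels
and synapses in declaration order).

Units follow the closed system used throughout the package: capacitance in
µF, conductance in µS, voltage in mV, current in nA, time in s, concentration
in mM (so the pool scaling constant k2 is taken in mM/nA).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cpgsim")

__all__ = [
    "NetworkSchemaError",
    "NetworkReferenceError",
    "NetworkValueError",
    "GateSpec",
    "RegulationLink",
    "ChannelSpec",
    "IonPoolSpec",
    "CompartmentSpec",
    "NeuronSpec",
    "ElectricalSynapseSpec",
    "Facilitation",
    "Depression",
    "VoltageDependence",
    "ChemicalSynapseSpec",
    "NoiseTargetSpec",
    "StimulusSpec",
    "SimulationConfig",
    "NetworkSpec",
    "validate_network",
    "load_network",
    "save_network",
    "set_workbook_value",
    "spec_digest",
    "write_traces",
    "read_traces",
]


class NetworkSchemaError(Exception):
    """Workbook structure problem: missing sheet, unknown or missing column."""


class NetworkReferenceError(Exception):
    """A row names an entity (compartment, pool, channel) that does not exist."""


class NetworkValueError(Exception):
    """A numeric value is missing, non-numeric, or outside its allowed range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """Sigmoid steady-state gate with first-order kinetics.

    Steady state is 1/(1+exp((h-V)/s)); a negative slope factor ``s`` gives a
    falling (inactivation-type) sigmoid.  The time constant is either the
    constant ``tau`` (seconds) or voltage dependent,
    tau(V) = tau_base + tau_amp/(1+exp((tau_h-V)/tau_s)).
    """

    h: float
    s: float
    tau: float | None = None
    tau_base: float | None = None
    tau_amp: float | None = None
    tau_h: float | None = None
    tau_s: float | None = None

    @property
    def voltage_dependent_tau(self) -> bool:
        return self.tau_base is not None


@dataclass(frozen=True)
class RegulationLink:
    """Second-messenger regulation of a maximal conductance by a pool.

    ``saturating_activation``: f = γc/(1+γc) (0 at rest, saturates at 1).
    ``inhibition``: f = 1/(1+γc) (1 at rest, negative feedback).
    """

    pool: str
    form: str  # "saturating_activation" | "inhibition"
    gamma: float


@dataclass(frozen=True)
class ChannelSpec:
    """Voltage-dependent conductance: I = ḡ·A^p·B^q·(V−E)·f[reg]."""

    name: str
    gbar: float
    E: float
    activation: GateSpec | None = None
    p: int = 0
    inactivation: GateSpec | None = None
    q: int = 0
    regulation: RegulationLink | None = None
    feeds_pool: str | None = None


@dataclass(frozen=True)
class IonPoolSpec:
    """Lumped intracellular ion pool: dc/dt = k1·(−k2·I_src − c).

    k1 (s⁻¹) sets the decay rate, k2 (mM/nA) scales the summed source-channel
    current; an inward (negative) current accumulates concentration.
    """

    name: str
    k1: float
    k2: float
    source_channels: tuple[str, ...] = ()
    c_init: float = 0.0


@dataclass(frozen=True)
class CompartmentSpec:
    name: str
    Cm: float
    channels: tuple[ChannelSpec, ...] = ()
    pools: tuple[IonPoolSpec, ...] = ()
    V_init: float | None = None


@dataclass(frozen=True)
class NeuronSpec:
    """A neuron as one or more electrically coupled point compartments."""

    name: str
    compartments: tuple[CompartmentSpec, ...]
    coupling: tuple[tuple[str, str, float], ...] = ()


@dataclass(frozen=True)
class ElectricalSynapseSpec:
    """Resistive (gap-junction) coupling; current into i is ḡ·(Vi−Vj)."""

    cell_i: str
    cell_j: str
    gbar: float
    rectifying: bool = False


@dataclass(frozen=True)
class Facilitation:
    """Synaptic gain 1+γ_f·c driven by a presynaptic ion pool."""

    pool: str
    gamma_f: float


@dataclass(frozen=True)
class Depression:
    """Resource depression: d ← d·(1−u) per spike, dd/dt = (1−d)/τ_rec."""

    u: float
    tau_rec: float


@dataclass(frozen=True)
class VoltageDependence:
    """Postsynaptic voltage gating M2, first-order toward a sigmoid of V."""

    h: float
    s: float
    tau_m2: float


@dataclass(frozen=True)
class ChemicalSynapseSpec:
    """Event-triggered dual-exponential conductance with optional plasticity."""

    pre: str
    post: str
    w: float
    E: float
    tau_rise: float
    tau_decay: float
    threshold: float = 0.0
    facilitation: Facilitation | None = None
    depression: Depression | None = None
    voltage_dependence: VoltageDependence | None = None


@dataclass(frozen=True)
class NoiseTargetSpec:
    """Balanced Poisson background input onto one compartment.

    The user fixes the inhibitory weight w_i; the excitatory weight is derived
    at run time so the mean inhibitory and excitatory driving currents cancel
    at the resting potential.
    """

    target: str
    rate_i: float
    rate_e: float
    w_i: float
    tau_i: float
    tau_e: float
    E_i: float = -90.0
    E_e: float = 60.0
    seed: int | None = None


@dataclass(frozen=True)
class StimulusSpec:
    target: str
    kind: str  # "current_pulse" | "holding_current"
    amplitude: float
    t_start: float | None = None
    t_end: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    duration: float
    method: str = "adaptive"  # forward_euler | semi_implicit_cn | adaptive
    dt: float = 1e-4
    abstol: float = 1e-6
    reltol: float = 1e-8
    relax_max: float = 1.0
    relax_dvdt_tol: float = 1e-3
    record: tuple[tuple[str, str], ...] = ()
    seed: int = 0
    record_dt: float = 1e-3


@dataclass(frozen=True)
class NetworkSpec:
    """Immutable, validated network description."""

    neurons: tuple[NeuronSpec, ...]
    electrical_synapses: tuple[ElectricalSynapseSpec, ...] = ()
    chemical_synapses: tuple[ChemicalSynapseSpec, ...] = ()
    noise: tuple[NoiseTargetSpec, ...] = ()
    stimuli: tuple[StimulusSpec, ...] = ()
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(1.0))

    # -- naming ------------------------------------------------------------
    def compartment_ids(self) -> list[str]:
        """Full compartment ids: bare neuron name when single-compartment,
        otherwise ``neuron.compartment``."""
        out = []
        for n in self.neurons:
            if len(n.compartments) == 1:
                out.append(n.name)
            else:
                out.extend(f"{n.name}.{c.name}" for c in n.compartments)
        return out

    def compartment(self, cid: str) -> CompartmentSpec:
        n, c = self._split(cid)
        return c

    def _split(self, cid: str) -> tuple[NeuronSpec, CompartmentSpec]:
        if "." in cid:
            nname, cname = cid.split(".", 1)
        else:
            nname, cname = cid, None
        for n in self.neurons:
            if n.name != nname:
                continue
            if cname is None:
                if len(n.compartments) == 1:
                    return n, n.compartments[0]
                raise NetworkReferenceError(
                    f"'{cid}' is ambiguous: neuron '{nname}' has "
                    f"{len(n.compartments)} compartments"
                )
            for c in n.compartments:
                if c.name == cname:
                    return n, c
        raise NetworkReferenceError(f"unknown compartment '{cid}'")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_gate(g: GateSpec, where: str) -> None:
    if g.s == 0:
        raise NetworkValueError(f"{where}: slope factor s must be nonzero")
    if g.voltage_dependent_tau:
        if g.tau is not None:
            raise NetworkValueError(
                f"{where}: give either a constant tau or tau_base/amp/h/s, not both")
        for fld in ("tau_base", "tau_amp", "tau_h", "tau_s"):
            if getattr(g, fld) is None:
                raise NetworkValueError(f"{where}: voltage-dependent tau needs {fld}")
        if g.tau_base <= 0 or g.tau_base + g.tau_amp <= 0:
            raise NetworkValueError(f"{where}: tau(V) must stay positive")
        if g.tau_s == 0:
            raise NetworkValueError(f"{where}: tau slope factor must be nonzero")
    else:
        if g.tau is None or g.tau <= 0:
            raise NetworkValueError(f"{where}: gate time constant must be > 0")


def validate_network(spec: NetworkSpec) -> None:
    """Raise a diagnostic error unless every invariant of the spec holds."""
    comp_ids = spec.compartment_ids()
    if len(set(comp_ids)) != len(comp_ids):
        dup = sorted({c for c in comp_ids if comp_ids.count(c) > 1})
        raise NetworkValueError(f"duplicate compartment ids: {dup}")
    names = [n.name for n in spec.neurons]
    if len(set(names)) != len(names):
        raise NetworkValueError("neuron names must be unique")

    for n in spec.neurons:
        cnames = [c.name for c in n.compartments]
        if len(set(cnames)) != len(cnames):
            raise NetworkValueError(f"neuron '{n.name}': duplicate compartment names")
        if not n.compartments:
            raise NetworkValueError(f"neuron '{n.name}': needs at least one compartment")
        for a, b, g in n.coupling:
            for end in (a, b):
                if end.split(".", 1)[-1] not in cnames:
                    raise NetworkReferenceError(
                        f"neuron '{n.name}': coupling endpoint '{end}' not a compartment")
            if g < 0:
                raise NetworkValueError(f"neuron '{n.name}': coupling conductance < 0")
        for c in n.compartments:
            where = f"{n.name}.{c.name}"
            if c.Cm <= 0:
                raise NetworkValueError(f"{where}: Cm must be > 0")
            chnames = [ch.name for ch in c.channels]
            if len(set(chnames)) != len(chnames):
                raise NetworkValueError(f"{where}: duplicate channel names")
            pnames = [p.name for p in c.pools]
            if len(set(pnames)) != len(pnames):
                raise NetworkValueError(f"{where}: duplicate pool names")
            for p in c.pools:
                if p.k1 <= 0:
                    raise NetworkValueError(f"{where}.{p.name}: k1 must be > 0")
                if p.k2 < 0:
                    raise NetworkValueError(f"{where}.{p.name}: k2 must be >= 0")
                if p.c_init < 0:
                    raise NetworkValueError(f"{where}.{p.name}: c_init must be >= 0")
                for src in p.source_channels:
                    if src not in chnames:
                        raise NetworkReferenceError(
                            f"{where}.{p.name}: source channel '{src}' not found")
            for ch in c.channels:
                cw = f"{where}.{ch.name}"
                if ch.gbar < 0:
                    raise NetworkValueError(f"{cw}: gbar must be >= 0")
                if ch.q not in (0, 1):
                    raise NetworkValueError(f"{cw}: q must be 0 or 1")
                if ch.p < 0:
                    raise NetworkValueError(f"{cw}: p must be >= 0")
                if ch.p < ch.q:
                    raise NetworkValueError(f"{cw}: requires p >= q")
                if ch.activation is not None:
                    _check_gate(ch.activation, cw + " activation")
                elif ch.p != 0:
                    raise NetworkValueError(f"{cw}: p > 0 but no activation gate")
                if ch.inactivation is not None:
                    _check_gate(ch.inactivation, cw + " inactivation")
                elif ch.q != 0:
                    raise NetworkValueError(f"{cw}: q = 1 but no inactivation gate")
                if ch.regulation is not None:
                    r = ch.regulation
                    if r.form not in ("saturating_activation", "inhibition"):
                        raise NetworkValueError(f"{cw}: unknown regulation form '{r.form}'")
                    if r.gamma < 0:
                        raise NetworkValueError(f"{cw}: gamma must be >= 0")
                    if r.pool not in pnames:
                        raise NetworkReferenceError(
                            f"{cw}: regulation pool '{r.pool}' not in compartment {where}")
                if ch.feeds_pool is not None and ch.feeds_pool not in pnames:
                    raise NetworkReferenceError(
                        f"{cw}: feeds_pool '{ch.feeds_pool}' not in compartment {where}")

    def _resolve(cid: str, what: str) -> CompartmentSpec:
        try:
            return spec.compartment(cid)
        except NetworkReferenceError as exc:
            raise NetworkReferenceError(f"{what}: {exc}") from None

    for es in spec.electrical_synapses:
        if es.cell_i == es.cell_j:
            raise NetworkValueError(
                f"electrical synapse {es.cell_i}<->{es.cell_j}: endpoints must differ")
        if es.gbar < 0:
            raise NetworkValueError(
                f"electrical synapse {es.cell_i}<->{es.cell_j}: gbar must be >= 0")
        _resolve(es.cell_i, f"electrical synapse to '{es.cell_j}'")
        _resolve(es.cell_j, f"electrical synapse from '{es.cell_i}'")

    for cs in spec.chemical_synapses:
        cw = f"chemical synapse {cs.pre}->{cs.post}"
        pre = _resolve(cs.pre, cw)
        _resolve(cs.post, cw)
        if cs.w < 0:
            raise NetworkValueError(f"{cw}: weight must be >= 0")
        if not (cs.tau_decay > cs.tau_rise > 0):
            raise NetworkValueError(f"{cw}: requires tau_decay > tau_rise > 0")
        if cs.facilitation is not None:
            if cs.facilitation.gamma_f < 0:
                raise NetworkValueError(f"{cw}: gamma_f must be >= 0")
            if cs.facilitation.pool not in [p.name for p in pre.pools]:
                raise NetworkReferenceError(
                    f"{cw}: facilitation pool '{cs.facilitation.pool}' "
                    f"not on presynaptic compartment '{cs.pre}'")
        if cs.depression is not None:
            if not 0 <= cs.depression.u <= 1:
                raise NetworkValueError(f"{cw}: u must be in [0, 1]")
            if cs.depression.tau_rec <= 0:
                raise NetworkValueError(f"{cw}: tau_rec must be > 0")
        if cs.voltage_dependence is not None:
            vd = cs.voltage_dependence
            if vd.s == 0:
                raise NetworkValueError(f"{cw}: voltage-dependence slope must be nonzero")
            if vd.tau_m2 <= 0:
                raise NetworkValueError(f"{cw}: tau_m2 must be > 0")

    for nt in spec.noise:
        _resolve(nt.target, "noise target")
        if nt.rate_i < 0 or nt.rate_e < 0:
            raise NetworkValueError(f"noise on '{nt.target}': rates must be >= 0")
        if nt.w_i < 0:
            raise NetworkValueError(f"noise on '{nt.target}': w_i must be >= 0")
        if nt.tau_i <= 0 or nt.tau_e <= 0:
            raise NetworkValueError(f"noise on '{nt.target}': taus must be > 0")

    for st in spec.stimuli:
        _resolve(st.target, "stimulus target")
        if st.kind not in ("current_pulse", "holding_current"):
            raise NetworkValueError(f"stimulus on '{st.target}': unknown kind '{st.kind}'")
        if st.kind == "current_pulse":
            if st.t_start is None or st.t_end is None or not st.t_end > st.t_start:
                raise NetworkValueError(
                    f"stimulus on '{st.target}': pulse needs t_end > t_start")

    sim = spec.sim
    if sim.duration <= 0:
        raise NetworkValueError("simulation duration must be > 0")
    if sim.method not in ("forward_euler", "semi_implicit_cn", "adaptive"):
        raise NetworkValueError(f"unknown integration method '{sim.method}'")
    if sim.method in ("forward_euler", "semi_implicit_cn") and sim.dt <= 0:
        raise NetworkValueError("fixed-step methods require dt > 0")
    if sim.relax_max <= 0 or sim.relax_max > 10:
        raise NetworkValueError("relax_max must be in (0, 10] s")
    for comp, qty in sim.record:
        _resolve(comp, "record request")


# ---------------------------------------------------------------------------
# Workbook schema
# ---------------------------------------------------------------------------

MANDATORY_SHEETS = (
    "Neurons", "Channels", "Pools", "ElectricalSynapses",
    "ChemicalSynapses", "Stimuli", "Simulation",
)
OPTIONAL_SHEETS = ("Noise",)

_SHEET_COLUMNS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # sheet: (required columns, optional columns)
    "Neurons": (("neuron", "compartment", "Cm"), ("V_init",)),
    "Channels": (
        ("neuron", "compartment", "channel", "gbar", "E"),
        ("p", "q",
         "act_h", "act_s", "act_tau", "act_tau_base", "act_tau_amp",
         "act_tau_h", "act_tau_s",
         "inact_h", "inact_s", "inact_tau", "inact_tau_base", "inact_tau_amp",
         "inact_tau_h", "inact_tau_s",
         "regulation_pool", "regulation_form", "regulation_gamma", "feeds_pool"),
    ),
    "Pools": (("neuron", "compartment", "pool", "k1", "k2"), ("c_init",)),
    "ElectricalSynapses": (("cell_i", "cell_j", "gbar"), ("rectifying",)),
    "ChemicalSynapses": (
        ("pre", "post", "w", "E", "tau_rise", "tau_decay"),
        ("threshold", "fac_pool", "fac_gamma", "dep_u", "dep_tau_rec",
         "vd_h", "vd_s", "vd_tau"),
    ),
    "Noise": (
        ("target", "w_i"),
        ("rate_i", "rate_e", "interval_i", "interval_e",
         "tau_i", "tau_e", "E_i", "E_e", "seed"),
    ),
    "Stimuli": (("target", "kind", "amplitude"), ("t_start", "t_end")),
    "Simulation": (
        ("duration",),
        ("method", "dt", "abstol", "reltol", "relax_max", "relax_dvdt_tol",
         "record", "seed", "record_dt"),
    ),
}


def _is_blank(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


class _Row:
    """One workbook row with diagnostic-carrying typed accessors."""

    def __init__(self, sheet: str, index: int, data: Mapping):
        self.sheet, self.index, self.data = sheet, index, data

    def _where(self, col: str) -> str:
        return f"sheet '{self.sheet}', row {self.index}, column '{col}'"

    def num(self, col: str, required: bool = False, default=None,
            minimum=None, strict_min=None):
        v = self.data.get(col)
        if _is_blank(v):
            if required:
                raise NetworkValueError(f"{self._where(col)}: value required")
            return default
        try:
            x = float(v)
        except (TypeError, ValueError):
            raise NetworkValueError(f"{self._where(col)}: not numeric: {v!r}") from None
        if not math.isfinite(x):
            raise NetworkValueError(f"{self._where(col)}: not finite: {v!r}")
        if minimum is not None and x < minimum:
            raise NetworkValueError(f"{self._where(col)}: must be >= {minimum}, got {x}")
        if strict_min is not None and x <= strict_min:
            raise NetworkValueError(f"{self._where(col)}: must be > {strict_min}, got {x}")
        return x

    def integer(self, col: str, required: bool = False, default=None, minimum=None):
        x = self.num(col, required=required, minimum=minimum)
        if x is None:
            return default
        if x != int(x):
            raise NetworkValueError(f"{self._where(col)}: must be an integer, got {x}")
        return int(x)

    def text(self, col: str, required: bool = False, default=None):
        v = self.data.get(col)
        if _is_blank(v):
            if required:
                raise NetworkValueError(f"{self._where(col)}: value required")
            return default
        return str(v).strip()

    def boolean(self, col: str, default=False):
        v = self.data.get(col)
        if _is_blank(v):
            return default
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise NetworkValueError(f"{self._where(col)}: not a boolean: {v!r}")


def _sheet_rows(frames: Mapping[str, pd.DataFrame], sheet: str) -> list[_Row]:
    df = frames[sheet]
    req, opt = _SHEET_COLUMNS[sheet]
    known = set(req) | set(opt)
    cols = [str(c) for c in df.columns]
    unknown = [c for c in cols if c not in known and not c.startswith("Unnamed")]
    if unknown:
        raise NetworkSchemaError(f"sheet '{sheet}': unknown columns {unknown}")
    missing = [c for c in req if c not in cols]
    if missing:
        raise NetworkSchemaError(f"sheet '{sheet}': missing required columns {missing}")
    rows = []
    for i, (_, rec) in enumerate(df.iterrows(), start=1):
        d = {str(k): v for k, v in rec.items()}
        if all(_is_blank(v) for v in d.values()):
            continue
        rows.append(_Row(sheet, i, d))
    return rows


def _parse_gate(row: _Row, prefix: str) -> GateSpec | None:
    h = row.num(f"{prefix}_h")
    if h is None:
        return None
    s = row.num(f"{prefix}_s", required=True)
    tau = row.num(f"{prefix}_tau")
    base = row.num(f"{prefix}_tau_base")
    if base is not None:
        g = GateSpec(h=h, s=s, tau=None, tau_base=base,
                     tau_amp=row.num(f"{prefix}_tau_amp", required=True),
                     tau_h=row.num(f"{prefix}_tau_h", required=True),
                     tau_s=row.num(f"{prefix}_tau_s", required=True))
    else:
        if tau is None:
            raise NetworkValueError(
                f"sheet '{row.sheet}', row {row.index}: gate '{prefix}' needs "
                f"{prefix}_tau or {prefix}_tau_base/...")
        g = GateSpec(h=h, s=s, tau=tau)
    return g


def _frames_to_spec(frames: Mapping[str, pd.DataFrame]) -> NetworkSpec:
    for sheet in MANDATORY_SHEETS:
        if sheet not in frames:
            raise NetworkSchemaError(f"missing mandatory sheet '{sheet}'")
    for sheet in frames:
        if sheet not in MANDATORY_SHEETS + OPTIONAL_SHEETS:
            logger.warning("ignoring unknown sheet '%s'", sheet)

    # Neurons / compartments ------------------------------------------------
    comp_rows: dict[str, list[_Row]] = {}
    order: list[str] = []
    for row in _sheet_rows(frames, "Neurons"):
        n = row.text("neuron", required=True)
        comp_rows.setdefault(n, []).append(row)
        if n not in order:
            order.append(n)

    # Channels and pools grouped per (neuron, compartment)
    chan_rows: dict[tuple[str, str | None], list[_Row]] = {}
    for row in _sheet_rows(frames, "Channels"):
        key = (row.text("neuron", required=True), row.text("compartment"))
        chan_rows.setdefault(key, []).append(row)
    pool_rows: dict[tuple[str, str | None], list[_Row]] = {}
    for row in _sheet_rows(frames, "Pools"):
        key = (row.text("neuron", required=True), row.text("compartment"))
        pool_rows.setdefault(key, []).append(row)

    def _take(groups, neuron: str, comp: str, single: bool) -> list[_Row]:
        out = list(groups.get((neuron, comp), ()))
        if single:
            out += groups.get((neuron, None), ())
        return out

    neurons = []
    for nname in sorted(order):  # canonical: neurons alphabetical
        rows = comp_rows[nname]
        single = len(rows) == 1
        comps = []
        for row in rows:
            cname = row.text("compartment", default="soma")
            channels = []
            feeds: dict[str, list[str]] = {}
            for cr in _take(chan_rows, nname, cname, single):
                chname = cr.text("channel", required=True)
                act = _parse_gate(cr, "act")
                inact = _parse_gate(cr, "inact")
                p = cr.integer("p", default=1 if act is not None else 0, minimum=0)
                q = cr.integer("q", default=1 if inact is not None else 0, minimum=0)
                reg_pool = cr.text("regulation_pool")
                reg = None
                if reg_pool is not None:
                    reg = RegulationLink(
                        pool=reg_pool,
                        form=cr.text("regulation_form", required=True),
                        gamma=cr.num("regulation_gamma", required=True, minimum=0.0),
                    )
                fp = cr.text("feeds_pool")
                if fp is not None:
                    feeds.setdefault(fp, []).append(chname)
                channels.append(ChannelSpec(
                    name=chname,
                    gbar=cr.num("gbar", required=True, minimum=0.0),
                    E=cr.num("E", required=True),
                    activation=act, p=p, inactivation=inact, q=q,
                    regulation=reg, feeds_pool=fp,
                ))
            pools = []
            for pr in _take(pool_rows, nname, cname, single):
                pname = pr.text("pool", required=True)
                pools.append(IonPoolSpec(
                    name=pname,
                    k1=pr.num("k1", required=True, strict_min=0.0),
                    k2=pr.num("k2", required=True, minimum=0.0),
                    source_channels=tuple(feeds.get(pname, ())),
                    c_init=pr.num("c_init", default=0.0, minimum=0.0),
                ))
            comps.append(CompartmentSpec(
                name=cname,
                Cm=row.num("Cm", required=True, strict_min=0.0),
                channels=tuple(channels),
                pools=tuple(pools),
                V_init=row.num("V_init"),
            ))
        neurons.append(NeuronSpec(name=nname, compartments=tuple(comps)))

    # Electrical synapses; intra-neuron rows become NeuronSpec.coupling -----
    elec, coupling = [], {}
    for row in _sheet_rows(frames, "ElectricalSynapses"):
        ci = row.text("cell_i", required=True)
        cj = row.text("cell_j", required=True)
        g = row.num("gbar", required=True, minimum=0.0)
        rect = row.boolean("rectifying", default=False)
        ni, nj = ci.split(".", 1)[0], cj.split(".", 1)[0]
        if ni == nj:
            coupling.setdefault(ni, []).append((ci, cj, g))
        else:
            elec.append(ElectricalSynapseSpec(ci, cj, g, rect))
    if coupling:
        neurons = [
            dataclasses.replace(n, coupling=tuple(coupling.get(n.name, ())))
            for n in neurons
        ]

    chem = []
    for row in _sheet_rows(frames, "ChemicalSynapses"):
        fac_pool = row.text("fac_pool")
        fac = (Facilitation(fac_pool, row.num("fac_gamma", required=True, minimum=0.0))
               if fac_pool is not None else None)
        u = row.num("dep_u")
        dep = (Depression(u, row.num("dep_tau_rec", required=True, strict_min=0.0))
               if u is not None else None)
        vh = row.num("vd_h")
        vd = (VoltageDependence(vh, row.num("vd_s", required=True),
                                row.num("vd_tau", required=True, strict_min=0.0))
              if vh is not None else None)
        chem.append(ChemicalSynapseSpec(
            pre=row.text("pre", required=True),
            post=row.text("post", required=True),
            w=row.num("w", required=True, minimum=0.0),
            E=row.num("E", required=True),
            tau_rise=row.num("tau_rise", required=True, strict_min=0.0),
            tau_decay=row.num("tau_decay", required=True, strict_min=0.0),
            threshold=row.num("threshold", default=0.0),
            facilitation=fac, depression=dep, voltage_dependence=vd,
        ))

    noise = []
    if "Noise" in frames:
        for row in _sheet_rows(frames, "Noise"):
            rate_i = row.num("rate_i")
            if rate_i is None:
                iv = row.num("interval_i")
                rate_i = 1000.0 / iv if iv else 0.0  # interval given in ms
            rate_e = row.num("rate_e")
            if rate_e is None:
                iv = row.num("interval_e")
                rate_e = 1000.0 / iv if iv else rate_i  # rates equal by default
            tau_i = row.num("tau_i", default=0.025, strict_min=0.0)
            noise.append(NoiseTargetSpec(
                target=row.text("target", required=True),
                rate_i=rate_i, rate_e=rate_e,
                w_i=row.num("w_i", required=True, minimum=0.0),
                tau_i=tau_i,
                tau_e=row.num("tau_e", default=tau_i, strict_min=0.0),
                E_i=row.num("E_i", default=-90.0),
                E_e=row.num("E_e", default=60.0),
                seed=row.integer("seed"),
            ))

    stimuli = []
    for row in _sheet_rows(frames, "Stimuli"):
        stimuli.append(StimulusSpec(
            target=row.text("target", required=True),
            kind=row.text("kind", required=True),
            amplitude=row.num("amplitude", required=True),
            t_start=row.num("t_start"),
            t_end=row.num("t_end"),
        ))

    sim_rows = _sheet_rows(frames, "Simulation")
    if not sim_rows:
        raise NetworkValueError("sheet 'Simulation': needs one row")
    sr = sim_rows[0]
    record: list[tuple[str, str]] = []
    rec_text = sr.text("record")
    if rec_text:
        for item in rec_text.split(";"):
            item = item.strip()
            if not item:
                continue
            comp, _, qty = item.partition(":")
            record.append((comp.strip(), (qty or "V").strip()))
    sim = SimulationConfig(
        duration=sr.num("duration", required=True, strict_min=0.0),
        method=sr.text("method", default="adaptive"),
        dt=sr.num("dt", default=1e-4, strict_min=0.0),
        abstol=sr.num("abstol", default=1e-6, strict_min=0.0),
        reltol=sr.num("reltol", default=1e-8, strict_min=0.0),
        relax_max=sr.num("relax_max", default=1.0, strict_min=0.0),
        relax_dvdt_tol=sr.num("relax_dvdt_tol", default=1e-3, strict_min=0.0),
        record=tuple(record),
        seed=sr.integer("seed", default=0),
        record_dt=sr.num("record_dt", default=1e-3, strict_min=0.0),
    )

    spec = NetworkSpec(
        neurons=tuple(neurons),
        electrical_synapses=tuple(elec),
        chemical_synapses=tuple(chem),
        noise=tuple(noise),
        stimuli=tuple(stimuli),
        sim=sim,
    )
    validate_network(spec)
    return spec


def _gate_cells(g: GateSpec | None, prefix: str) -> dict:
    if g is None:
        return {}
    out = {f"{prefix}_h": g.h, f"{prefix}_s": g.s}
    if g.voltage_dependent_tau:
        out.update({f"{prefix}_tau_base": g.tau_base, f"{prefix}_tau_amp": g.tau_amp,
                    f"{prefix}_tau_h": g.tau_h, f"{prefix}_tau_s": g.tau_s})
    else:
        out[f"{prefix}_tau"] = g.tau
    return out


def _spec_to_frames(spec: NetworkSpec) -> dict[str, pd.DataFrame]:
    neurons = sorted(spec.neurons, key=lambda n: n.name)

    nrows, chrows, prows = [], [], []
    for n in neurons:
        single = len(n.compartments) == 1
        for c in n.compartments:
            nrows.append({"neuron": n.name, "compartment": c.name,
                          "Cm": c.Cm, "V_init": c.V_init})
            for ch in c.channels:
                rec = {"neuron": n.name, "compartment": c.name, "channel": ch.name,
                       "gbar": ch.gbar, "E": ch.E, "p": ch.p, "q": ch.q}
                rec.update(_gate_cells(ch.activation, "act"))
                rec.update(_gate_cells(ch.inactivation, "inact"))
                if ch.regulation is not None:
                    rec.update({"regulation_pool": ch.regulation.pool,
                                "regulation_form": ch.regulation.form,
                                "regulation_gamma": ch.regulation.gamma})
                if ch.feeds_pool is not None:
                    rec["feeds_pool"] = ch.feeds_pool
                chrows.append(rec)
            for p in c.pools:
                prows.append({"neuron": n.name, "compartment": c.name, "pool": p.name,
                              "k1": p.k1, "k2": p.k2, "c_init": p.c_init})

    erows = []
    for n in neurons:
        for a, b, g in n.coupling:
            erows.append({"cell_i": a, "cell_j": b, "gbar": g, "rectifying": False})
    for es in spec.electrical_synapses:
        erows.append({"cell_i": es.cell_i, "cell_j": es.cell_j,
                      "gbar": es.gbar, "rectifying": es.rectifying})

    crows = []
    for cs in spec.chemical_synapses:
        rec = {"pre": cs.pre, "post": cs.post, "w": cs.w, "E": cs.E,
               "tau_rise": cs.tau_rise, "tau_decay": cs.tau_decay,
               "threshold": cs.threshold}
        if cs.facilitation is not None:
            rec.update({"fac_pool": cs.facilitation.pool,
                        "fac_gamma": cs.facilitation.gamma_f})
        if cs.depression is not None:
            rec.update({"dep_u": cs.depression.u,
                        "dep_tau_rec": cs.depression.tau_rec})
        if cs.voltage_dependence is not None:
            rec.update({"vd_h": cs.voltage_dependence.h,
                        "vd_s": cs.voltage_dependence.s,
                        "vd_tau": cs.voltage_dependence.tau_m2})
        crows.append(rec)

    xrows = []
    for nt in spec.noise:
        xrows.append({"target": nt.target, "rate_i": nt.rate_i, "rate_e": nt.rate_e,
                      "w_i": nt.w_i, "tau_i": nt.tau_i, "tau_e": nt.tau_e,
                      "E_i": nt.E_i, "E_e": nt.E_e, "seed": nt.seed})

    srows = [{"target": st.target, "kind": st.kind, "amplitude": st.amplitude,
              "t_start": st.t_start, "t_end": st.t_end} for st in spec.stimuli]

    sim = spec.sim
    simrow = {"duration": sim.duration, "method": sim.method, "dt": sim.dt,
              "abstol": sim.abstol, "reltol": sim.reltol,
              "relax_max": sim.relax_max, "relax_dvdt_tol": sim.relax_dvdt_tol,
              "record": ";".join(f"{c}:{q}" for c, q in sim.record) or None,
              "seed": sim.seed, "record_dt": sim.record_dt}

    def _df(rows, sheet):
        req, opt = _SHEET_COLUMNS[sheet]
        cols = [c for c in req + opt if c not in ("interval_i", "interval_e")]
        return pd.DataFrame(rows, columns=cols)

    return {
        "Neurons": _df(nrows, "Neurons"),
        "Channels": _df(chrows, "Channels"),
        "Pools": _df(prows, "Pools"),
        "ElectricalSynapses": _df(erows, "ElectricalSynapses"),
        "ChemicalSynapses": _df(crows, "ChemicalSynapses"),
        "Noise": _df(xrows, "Noise"),
        "Stimuli": _df(srows, "Stimuli"),
        "Simulation": _df([simrow], "Simulation"),
    }


def load_network(path) -> NetworkSpec:
    """Parse a workbook into a validated :class:`NetworkSpec`."""
    frames = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    return _frames_to_spec(frames)


def save_network(spec: NetworkSpec, path) -> None:
    """Write ``spec`` to a workbook that reloads to an equal spec."""
    validate_network(spec)
    frames = _spec_to_frames(spec)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for sheet, df in frames.items():
            df.to_excel(xl, sheet_name=sheet, index=False)


def set_workbook_value(spec: NetworkSpec, address: str, value: float) -> NetworkSpec:
    """Return a new spec with one scalar changed, addressed as
    ``Sheet:row:column`` (row is the 1-based data row below the header).

    This is the parameter-sweep hook: any numeric workbook cell is sweepable.
    """
    try:
        sheet, row_s, col = address.split(":")
        irow = int(row_s)
    except ValueError:
        raise NetworkValueError(
            f"bad parameter address '{address}' (want Sheet:row:column)") from None
    frames = _spec_to_frames(spec)
    if sheet not in frames:
        raise NetworkSchemaError(f"parameter address: unknown sheet '{sheet}'")
    df = frames[sheet]
    if col not in df.columns:
        raise NetworkSchemaError(f"parameter address: unknown column '{col}' in '{sheet}'")
    if not 1 <= irow <= len(df):
        raise NetworkValueError(
            f"parameter address: row {irow} out of range for sheet '{sheet}' "
            f"({len(df)} rows)")
    df = df.copy()
    df.loc[df.index[irow - 1], col] = value
    frames = dict(frames)
    frames[sheet] = df
    return _frames_to_spec(frames)


def spec_digest(spec: NetworkSpec) -> str:
    """Stable content hash of a spec (used in run manifests)."""
    blob = json.dumps(dataclasses.asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Trace output
# ---------------------------------------------------------------------------

def write_traces(traces, path, format: str = "tsv") -> None:
    """Write a :class:`~cpgsim.runner.TraceSet` to disk.

    ``tsv``: first column time (s), one column per recorded quantity, header
    row ``cell:quantity``, full double precision.  ``binary-table``: an .npz
    archive that reads back bitwise identical.
    """
    if not traces.data:
        raise NetworkValueError("empty TraceSet")
    keys = list(traces.data)
    if format == "tsv":
        header = "time\t" + "\t".join(f"{c}:{q}" for c, q in keys)
        cols = [np.asarray(traces.time)] + [np.asarray(traces.data[k]) for k in keys]
        np.savetxt(path, np.column_stack(cols), delimiter="\t",
                   header=header, comments="", fmt="%.17g")
    elif format == "binary-table":
        arrays = {"time": np.asarray(traces.time)}
        for k in keys:
            arrays[f"{k[0]}:{k[1]}"] = np.asarray(traces.data[k])
        np.savez(path, __manifest__=json.dumps(traces.manifest, default=str), **arrays)
    else:
        raise NetworkValueError(f"unknown trace format '{format}'")


def read_traces(path, format: str = "tsv"):
    """Read a trace file written by :func:`write_traces`."""
    from .runner import TraceSet

    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        arr = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
        data = {}
        for j, name in enumerate(header[1:], start=1):
            comp, _, qty = name.partition(":")
            data[(comp, qty)] = arr[:, j]
        return TraceSet(time=arr[:, 0], data=data, manifest={})
    if format == "binary-table":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["__manifest__"]))
            data = {}
            for name in z.files:
                if name in ("time", "__manifest__"):
                    continue
                comp, _, qty = name.partition(":")
                data[(comp, qty)] = z[name]
            return TraceSet(time=z["time"], data=data, manifest=manifest)
    raise NetworkValueError(f"unknown trace format '{format}'")
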