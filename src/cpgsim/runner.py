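"""Run orchestration: build runtime model, relax, simulate, record.

``run_simulation`` is the single programmatic entry point used by the CLI and
the parameter sweep: it compiles the spec, runs the relaxation period with
stimuli and noise disabled, resolves the balanced noise weights against the
relaxed resting potentials, integrates for the requested duration, and
returns a :class:`TraceSet` whose time axis starts at 0 after relaxation.
"""

from __future__ import annotations

import dataclasses
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .dynamics import NetworkState, RuntimeNetwork
from .events_noise import spawn_noise_trains
from .integrators import (
    IntegrationReport,
    _NoiseFeed,
    integrate_adaptive,
    integrate_fixed,
    relax,
)
from .schema_io import NetworkSpec, NetworkValueError, spec_digest, validate_network

logger = logging.getLogger("cpgsim")

__all__ = ["TraceSet", "BatchFailure", "run_simulation", "run_batch"]


@dataclass
class TraceSet:
    """Recorded time series keyed by (compartment, quantity).

    Quantity names: ``V`` (mV), ``I_<channel>`` (nA), ``f_<channel>``
    (regulation factor), ``c_<pool>`` (mM), ``I_syn`` (total chemical
    synaptic current, nA), ``I_noise`` (nA).
    """

    time: np.ndarray
    data: dict[tuple[str, str], np.ndarray]
    manifest: dict
    events: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class BatchFailure:
    """Sentinel result for a failed batch item (failures are isolated)."""

    index: int
    error: str


def _derive_series(rt: RuntimeNetwork, times, snaps, comp: str, qty: str):
    """Compute one requested quantity from the extended-state snapshots."""
    nc, ng, npo, ns = rt.nc, rt.ng, rt.npool, rt.ns
    ci = rt.resolve(comp)
    V = snaps[:, :nc]
    gates = snaps[:, nc:nc + ng]
    pools = snaps[:, nc + ng:nc + ng + npo]
    base = nc + ng + npo
    m2 = snaps[:, base:base + ns]
    yr = snaps[:, base + ns:base + 2 * ns]
    yd = snaps[:, base + 2 * ns:base + 3 * ns]
    d = snaps[:, base + 3 * ns:base + 4 * ns]
    gi = snaps[:, base + 4 * ns:base + 4 * ns + rt.nnz]
    ge = snaps[:, base + 4 * ns + rt.nnz:]

    if qty == "V":
        return V[:, ci].copy()
    if qty.startswith("c_"):
        name = qty[2:]
        for pi, (cid, pname) in enumerate(rt.pool_names):
            if cid == rt.comp_ids[ci] and pname == name:
                return pools[:, pi].copy()
        raise NetworkValueError(f"no pool '{name}' on compartment '{comp}'")
    if qty.startswith(("I_", "f_")) and qty not in ("I_syn", "I_noise"):
        name = qty[2:]
        for chi, (cid, chname) in enumerate(rt.channel_names):
            if cid == rt.comp_ids[ci] and chname == name:
                break
        else:
            raise NetworkValueError(f"no channel '{name}' on compartment '{comp}'")
        out = np.empty(len(times))
        for k in range(len(times)):
            Ich, freg = rt.channel_currents(V[k], gates[k], pools[k])
            out[k] = Ich[chi] if qty.startswith("I_") else freg[chi]
        return out
    if qty == "I_syn":
        out = np.zeros(len(times))
        for si in range(ns):
            if rt.s_post[si] != ci:
                continue
            Y = rt.s_norm[si] * (yd[:, si] - yr[:, si])
            gain = 1.0
            if rt.s_fac_pool[si] >= 0:
                gain = 1.0 + rt.s_fac_gamma[si] * pools[:, rt.s_fac_pool[si]]
            M1 = Y * gain * d[:, si]
            out += rt.s_w[si] * M1 * m2[:, si] * (V[:, ci] - rt.s_E[si])
        return out
    if qty == "I_noise":
        out = np.zeros(len(times))
        for k in range(rt.nnz):
            if rt.nz_comp[k] != ci:
                continue
            out += gi[:, k] * (V[:, ci] - rt.nz_Ei[k]) \
                + ge[:, k] * (V[:, ci] - rt.nz_Ee[k])
        return out
    raise NetworkValueError(f"unknown quantity '{qty}'")


def run_simulation(spec: NetworkSpec, **overrides):
    """Relax, integrate, and record one network.

    Keyword overrides (``duration``, ``method``, ``dt``, ``seed``,
    ``abstol``, ``reltol``, ``record``, ``record_dt``, ``relax_max``,
    ``relax_dvdt_tol``) replace the corresponding Simulation-sheet fields.
    Returns ``(TraceSet, IntegrationReport)``; deterministic for fixed seed.
    """
    validate_network(spec)
    sim = dataclasses.replace(spec.sim, **overrides)
    rt = RuntimeNetwork(spec)

    st0 = rt.initial_state()
    st, relax_dur = relax(rt, st0, relax_max=sim.relax_max,
                          dvdt_tol=sim.relax_dvdt_tol, method=sim.method,
                          dt=sim.dt, abstol=sim.abstol, reltol=sim.reltol)
    logger.info("relaxation finished after %.3g s", relax_dur)

    V_r = {nt.target: float(st.V[rt.resolve(nt.target)]) for nt in spec.noise}
    realizations = spawn_noise_trains(spec.noise, sim.duration, sim.seed, V_r)
    feed = _NoiseFeed(rt, realizations)

    spike_log: dict[int, list] = {}
    if sim.method in ("forward_euler", "semi_implicit_cn"):
        stride = max(1, int(round(sim.record_dt / sim.dt)))
        st, times, snaps, n_ev, n_steps = integrate_fixed(
            rt, st, sim.duration, sim.dt, sim.method,
            record_stride=stride, noise=feed, spike_log=spike_log)
    elif sim.method == "adaptive":
        grid = np.arange(0.0, sim.duration + 0.5 * sim.record_dt, sim.record_dt)
        st, times, snaps, n_ev, n_steps = integrate_adaptive(
            rt, st, sim.duration, sim.abstol, sim.reltol,
            record_times=grid, noise=feed, spike_log=spike_log)
    else:
        raise NetworkValueError(f"unknown integration method '{sim.method}'")

    requested = list(sim.record) or [(cid, "V") for cid in rt.comp_ids]
    data = {}
    for comp, qty in requested:
        data[(rt.comp_ids[rt.resolve(comp)], qty)] = _derive_series(
            rt, times, snaps, comp, qty)

    manifest = {
        "spec": spec_digest(spec),
        "seed": sim.seed,
        "method": sim.method,
        "dt": sim.dt if sim.method != "adaptive" else None,
        "abstol": sim.abstol,
        "reltol": sim.reltol,
        "relax_duration": relax_dur,
        "noise_w_e": {r.target: r.w_e for r in realizations},
        "noise_V_r": V_r,
    }
    events = {rt.comp_ids[c]: np.array(ts) for c, ts in spike_log.items()}
    traces = TraceSet(time=times, data=data, manifest=manifest, events=events)
    report = IntegrationReport(
        method=sim.method, steps=n_steps,
        dt=sim.dt if sim.method != "adaptive" else None,
        abstol=sim.abstol if sim.method == "adaptive" else None,
        reltol=sim.reltol if sim.method == "adaptive" else None,
        relax_duration=relax_dur, event_count=n_ev)
    return traces, report


def _run_item(args):
    index, spec, overrides = args
    try:
        traces, report = run_simulation(spec, **overrides)
        return traces, report
    except Exception as exc:  # isolation: one failure must not kill the batch
        logger.warning("batch item %d failed: %s", index, exc)
        return BatchFailure(index, f"{type(exc).__name__}: {exc}")


def run_batch(items, batch_size: int = 1):
    """Run a list of ``(spec, overrides)`` items, ``batch_size`` at a time.

    Results are order-preserving and identical to serial execution; a failed
    item yields a :class:`BatchFailure` sentinel in its slot.
    """
    if batch_size < 1:
        raise NetworkValueError("batch_size must be >= 1")
    jobs = [(i, spec, dict(ov)) for i, (spec, ov) in enumerate(items)]
    if batch_size == 1 or len(jobs) <= 1:
        return [_run_item(j) for j in jobs]
    with ProcessPoolExecutor(max_workers=batch_size) as pool:
        return list(pool.map(_run_item, jobs))
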