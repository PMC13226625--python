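"""Time stepping: fixed-step explicit/semi-implicit, adaptive, relaxation.

Three integration methods advance a :class:`~cpgsim.dynamics.NetworkState`:

* ``forward_euler`` — y ← y + dt·f(y); first order.
* ``semi_implicit_cn`` — trapezoidal (Crank–Nicolson) step solved by fixed
  point iteration to 1e-10; second order on smooth problems, first order
  across input discontinuities.
* ``adaptive`` — scipy ``solve_ivp`` (LSODA, embedded error control),
  integrated piecewise between stimulus edges and noise events, with
  terminal event functions locating presynaptic threshold crossings.

Event-driven linear variables (synaptic kernel accumulators, depression
resource, noise conductances) decay exactly between boundaries and jump at
them, so the event-driven synaptic time course matches the kernel
convolution of the event train to round-off.

A relaxation period (stimuli and noise disabled) integrates until
max |dV/dt| falls below a tolerance, establishing initial conditions before
recording starts at t = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import NetworkState, RuntimeNetwork

logger = logging.getLogger("cpgsim")

__all__ = [
    "IntegrationError",
    "IntegrationReport",
    "step_forward_euler",
    "step_semi_implicit",
    "integrate_fixed",
    "integrate_adaptive",
    "relax",
    "convergence_slope",
    "REFRACTORY",
]

REFRACTORY = 2e-3  # s; merge window for presynaptic trigger crossings

_CN_TOL = 1e-10
_CN_MAXITER = 50


class IntegrationError(RuntimeError):
    """Integration failure (non-finite state, inner-iteration divergence)."""


@dataclass
class IntegrationReport:
    method: str
    steps: int
    dt: float | None
    abstol: float | None
    reltol: float | None
    relax_duration: float
    event_count: int


def _check_finite(rt: RuntimeNetwork, y: np.ndarray, t: float) -> None:
    if np.all(np.isfinite(y)):
        return
    bad = int(np.flatnonzero(~np.isfinite(y))[0])
    nc, ng = rt.nc, rt.ng
    if bad < nc:
        name = f"V[{rt.comp_ids[bad]}]"
    elif bad < nc + ng:
        name = f"gate[{bad - nc}]"
    elif bad < nc + ng + rt.npool:
        name = f"pool[{rt.pool_names[bad - nc - ng][1]}]"
    else:
        name = f"M2[{bad - nc - ng - rt.npool}]"
    raise IntegrationError(f"non-finite value in {name} at t = {t:.6g} s")


# ---------------------------------------------------------------------------
# Single fixed steps (smooth subsystem; aux decays exactly)
# ---------------------------------------------------------------------------

def _fe_smooth(rt: RuntimeNetwork, st: NetworkState, dt: float) -> np.ndarray:
    f0 = rt.derivative(st.t, st)
    return rt.pack_smooth(st) + dt * f0


def _cn_smooth(rt: RuntimeNetwork, st: NetworkState, dt: float,
               st_next: NetworkState) -> np.ndarray:
    """Trapezoidal step; ``st_next`` carries the (decayed) aux at t+dt and is
    used as scratch for the implicit evaluation."""
    y0 = rt.pack_smooth(st)
    f0 = rt.derivative(st.t, st)
    y = y0 + dt * f0  # explicit predictor
    t1 = st.t + dt
    scale = np.maximum(1.0, np.abs(y0))
    for _ in range(_CN_MAXITER):
        rt.unpack_smooth(y.copy(), st_next)
        f1 = rt.derivative(t1, st_next)
        y_new = y0 + 0.5 * dt * (f0 + f1)
        err = np.max(np.abs(y_new - y) / scale)
        y = y_new
        if err < _CN_TOL:
            return y
    raise IntegrationError(
        f"semi-implicit step failed to converge in {_CN_MAXITER} iterations "
        f"at t = {st.t:.6g} s")


def _detect_crossings(rt: RuntimeNetwork, st_old: NetworkState,
                      st_new: NetworkState, dt: float,
                      last_spike: dict[int, float]):
    """Upward threshold crossings of presynaptic compartments during a step.

    Returns [(t_cross, comp, syn_indices), ...], refractory-filtered.
    """
    hits = []
    for comp, thr, syn_idx in rt.trigger_groups:
        v0, v1 = st_old.V[comp], st_new.V[comp]
        if v0 < thr <= v1:
            tc = st_old.t + dt * (thr - v0) / (v1 - v0)
            if tc - last_spike.get(comp, -np.inf) > REFRACTORY:
                hits.append((tc, comp, syn_idx))
                last_spike[comp] = tc
    return hits


def step_forward_euler(rt: RuntimeNetwork, state: NetworkState,
                       dt: float) -> NetworkState:
    """One explicit step; presynaptic events detected against the new V are
    applied at the step boundary.  Returns a new state at t+dt."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = state.copy()
    y = _fe_smooth(rt, state, dt)
    _check_finite(rt, y, state.t)
    rt.unpack_smooth(y, new)
    rt.decay_events(new, dt)
    new.t = state.t + dt
    for tc, comp, syn_idx in _detect_crossings(rt, state, new, dt, {}):
        rt.apply_spikes(new, syn_idx)
    rt.clamp(new)
    return new


def step_semi_implicit(rt: RuntimeNetwork, state: NetworkState,
                       dt: float) -> NetworkState:
    """One Crank–Nicolson-style step (trapezoidal on the smooth variables,
    event states staggered exactly); events applied at the boundary."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = state.copy()
    rt.decay_events(new, dt)
    y = _cn_smooth(rt, state, dt, new.copy())
    _check_finite(rt, y, state.t)
    rt.unpack_smooth(y, new)
    new.t = state.t + dt
    for tc, comp, syn_idx in _detect_crossings(rt, state, new, dt, {}):
        rt.apply_spikes(new, syn_idx)
    rt.clamp(new)
    return new


# ---------------------------------------------------------------------------
# Fixed-step driver
# ---------------------------------------------------------------------------

class _NoiseFeed:
    """Cursor over the pre-generated per-target Poisson event trains."""

    def __init__(self, rt: RuntimeNetwork, realizations):
        self.active = bool(realizations) and rt.nnz > 0
        if not self.active:
            return
        self.ti = [r.train_i.times for r in realizations]
        self.te = [r.train_e.times for r in realizations]
        self.wi = rt.nz_wi
        self.we = np.array([r.w_e for r in realizations])
        self.pi = [0] * len(self.ti)
        self.pe = [0] * len(self.te)

    def all_times(self):
        if not self.active:
            return np.empty(0)
        parts = self.ti + self.te
        return np.unique(np.concatenate(parts)) if parts else np.empty(0)

    def apply_window(self, st: NetworkState, t0: float, t1: float) -> int:
        """Add w per event with time in (t0, t1]; returns event count."""
        if not self.active:
            return 0
        n_tot = 0
        for k, times in enumerate(self.ti):
            p = self.pi[k]
            while p < times.size and times[p] <= t1:
                if times[p] > t0:
                    st.noise_gi[k] += self.wi[k]
                    n_tot += 1
                p += 1
            self.pi[k] = p
        for k, times in enumerate(self.te):
            p = self.pe[k]
            while p < times.size and times[p] <= t1:
                if times[p] > t0:
                    st.noise_ge[k] += self.we[k]
                    n_tot += 1
                p += 1
            self.pe[k] = p
        return n_tot


def _extended(rt: RuntimeNetwork, st: NetworkState) -> np.ndarray:
    return np.concatenate([rt.pack_smooth(st), st.syn_yr, st.syn_yd,
                           st.syn_d, st.noise_gi, st.noise_ge])


def integrate_fixed(rt: RuntimeNetwork, state: NetworkState, t_end: float,
                    dt: float, method: str, record_stride: int = 1,
                    noise=None, spike_log: dict | None = None):
    """Advance ``state`` to ``t_end`` with a fixed-step method.

    Returns ``(state, times, snapshots, n_events, n_steps)`` where
    ``snapshots`` holds the extended state at every ``record_stride``-th step.
    """
    if method not in ("forward_euler", "semi_implicit_cn"):
        raise ValueError(f"unknown fixed-step method '{method}'")
    span = t_end - state.t
    n_steps = max(1, int(math.floor(span / dt + 1e-9)))
    remainder = span - n_steps * dt
    feed = noise if isinstance(noise, _NoiseFeed) else _NoiseFeed(rt, noise or [])
    last_spike: dict[int, float] = {}
    times = [state.t]
    snaps = [_extended(rt, state)]
    n_events = 0
    steps_done = 0
    fe = method == "forward_euler"
    check_every = max(1, min(1000, n_steps // 100 or 1))

    # working state whose smooth variables are views into one packed vector
    st = state.copy()
    y = rt.pack_smooth(st)
    rt.unpack_smooth(y, st)
    old = state.copy()  # scratch for crossing detection (V and t only)
    n_total = n_steps + (1 if remainder > 1e-12 else 0)
    for n in range(n_total):
        h = dt if n < n_steps else remainder
        old.V[:] = st.V
        old.t = st.t
        if fe:
            dy = rt.derivative(st.t, st)
            y += h * dy
            rt.decay_events(st, h)
        else:
            prev = st.copy()        # aux still at t
            rt.decay_events(st, h)  # aux at t+dt (pre-jump), per CN staggering
            y_new = _cn_smooth(rt, prev, h, st)
            y[:] = y_new
            rt.unpack_smooth(y, st)  # restore views after scratch unpacking
        st.t = old.t + h
        n_events += feed.apply_window(st, old.t, st.t)
        for tc, comp, syn_idx in _detect_crossings(rt, old, st, h, last_spike):
            rt.apply_spikes(st, syn_idx)
            n_events += 1
            if spike_log is not None:
                spike_log.setdefault(comp, []).append(tc)
        rt.clamp(st)
        steps_done += 1
        if steps_done % check_every == 0 or n == n_total - 1:
            _check_finite(rt, y, st.t)
        if steps_done % record_stride == 0 or n == n_total - 1:
            times.append(st.t)
            snaps.append(_extended(rt, st))
    return st, np.array(times), np.array(snaps), n_events, steps_done


# ---------------------------------------------------------------------------
# Adaptive driver
# ---------------------------------------------------------------------------

def integrate_adaptive(rt: RuntimeNetwork, state: NetworkState, t_end: float,
                       abstol: float, reltol: float,
                       record_times=None, noise=None,
                       spike_log: dict | None = None, max_step=np.inf):
    """Adaptive integration with error control and event localisation.

    Integrates piecewise between stimulus edges and noise-event times;
    presynaptic threshold crossings are located by the solver's root finding
    and the synaptic state jumps applied there.  Returns
    ``(state, times, snapshots, n_events, n_steps)`` with snapshots at the
    requested ``record_times`` (defaults to segment boundaries only).
    """
    if abstol <= 0 or reltol <= 0:
        raise ValueError("tolerances must be > 0")
    feed = noise if isinstance(noise, _NoiseFeed) else _NoiseFeed(rt, noise or [])
    grid = np.asarray(record_times) if record_times is not None else np.empty(0)

    # segment boundaries: stimulus edges and noise events inside (t, t_end)
    edges = []
    if rt.nst and rt.stimuli_enabled:
        for arr in (rt.st_t0, rt.st_t1):
            edges.extend(float(x) for x in arr if state.t < x < t_end and np.isfinite(x))
    nz_times = feed.all_times()
    edges.extend(float(x) for x in nz_times if state.t < x < t_end)
    boundaries = np.unique(np.array(edges + [t_end]))

    st = state
    times_out = [st.t]
    snaps = [_extended(rt, st)]
    n_events = 0
    n_steps = 0
    last_spike: dict[int, float] = {}

    def record_range(sol, aux_ref, t_from, t_to):
        """Record grid points in (t_from, t_to] using dense output for the
        smooth part and exact decay for the event-driven part."""
        sel = grid[(grid > t_from + 1e-15) & (grid <= t_to + 1e-15)]
        for tg in sel:
            y = sol.sol(tg)
            tmp = aux_ref.copy()
            rt.unpack_smooth(y.copy(), tmp)
            rt.decay_events(tmp, tg - aux_ref.t)
            tmp.t = tg
            times_out.append(tg)
            snaps.append(_extended(rt, tmp))

    for tb in boundaries:
        while st.t < tb - 1e-13:
            blank_until = None
            events = []
            emap = []
            for comp, thr, syn_idx in rt.trigger_groups:
                if st.t < last_spike.get(comp, -np.inf) + REFRACTORY - 1e-12:
                    # inside the merge window: integrate a short blanked span
                    blank_until = max(blank_until or 0.0,
                                      last_spike[comp] + REFRACTORY)
                    continue

                def ev(t, y, _c=comp, _thr=thr):
                    return y[_c] - _thr

                ev.terminal = True
                ev.direction = 1
                events.append(ev)
                emap.append((comp, thr, syn_idx))
            seg_end = tb if blank_until is None else min(tb, blank_until)
            if seg_end <= st.t + 1e-13:  # never issue a zero-width span
                st.t = seg_end if seg_end > st.t else st.t + 1e-13
                continue
            y0 = rt.pack_smooth(st)
            sol = solve_ivp(
                _adaptive_rhs(rt, st), (st.t, seg_end), y0, method="LSODA",
                rtol=reltol, atol=abstol, events=events or None,
                dense_output=True, max_step=max_step)
            if not sol.success:
                raise IntegrationError(
                    f"adaptive step failed at t = {st.t:.6g} s: {sol.message}")
            n_steps += sol.t.size - 1
            te = sol.t[-1]
            fired = None
            if sol.status == 1:
                # earliest triggered event
                cand = [(tev[0], k) for k, tev in enumerate(sol.t_events) if tev.size]
                te, k = min(cand)
                fired = emap[k]
            record_range(sol, st, st.t, te)
            new = st.copy()
            rt.unpack_smooth(sol.sol(te).copy(), new)
            rt.decay_events(new, te - st.t)
            new.t = te
            if fired is not None:
                comp, thr, syn_idx = fired
                rt.apply_spikes(new, syn_idx)
                last_spike[comp] = te
                n_events += 1
                if spike_log is not None:
                    spike_log.setdefault(comp, []).append(te)
            rt.clamp(new)
            _check_finite(rt, rt.pack_smooth(new), new.t)
            st = new
        # boundary reached: apply any noise events at exactly this time
        n_events += feed.apply_window(st, tb - 1e-13, tb + 1e-13)
        st.t = tb
    if grid.size == 0:
        times_out.append(st.t)
        snaps.append(_extended(rt, st))
    return st, np.array(times_out), np.array(snaps), n_events, n_steps


def _adaptive_rhs(rt: RuntimeNetwork, st_ref: NetworkState):
    """RHS closure for one smooth segment: event-driven variables follow
    their exact exponentials from the segment-start state ``st_ref``."""
    t0 = st_ref.t
    tmp = st_ref.copy()

    def rhs(t, y):
        rt.unpack_smooth(y.copy(), tmp)
        tmp.syn_yr = st_ref.syn_yr * np.exp(-(t - t0) / rt.s_taur) \
            if rt.ns else tmp.syn_yr
        tmp.syn_yd = st_ref.syn_yd * np.exp(-(t - t0) / rt.s_taud) \
            if rt.ns else tmp.syn_yd
        if rt.ns:
            dep = rt.s_dep
            tmp.syn_d = st_ref.syn_d.copy()
            tmp.syn_d[dep] = 1.0 + (st_ref.syn_d[dep] - 1.0) * np.exp(
                -(t - t0) / rt.s_taurec[dep])
        if rt.nnz:
            tmp.noise_gi = st_ref.noise_gi * np.exp(-(t - t0) / rt.nz_taui)
            tmp.noise_ge = st_ref.noise_ge * np.exp(-(t - t0) / rt.nz_taue)
        return rt.derivative(t, tmp)

    return rhs


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def relax(rt: RuntimeNetwork, state: NetworkState, relax_max: float = 1.0,
          dvdt_tol: float = 1e-3, method: str = "adaptive",
          dt: float = 1e-4, abstol: float = 1e-8, reltol: float = 1e-8):
    """Integrate with stimuli and noise disabled until max|dV/dt| < tol.

    Returns ``(state_at_rest, duration_used)``; recording restarts at t = 0.
    Hitting ``relax_max`` logs a warning (tonically active networks never
    settle) but is not an error.
    """
    saved = rt.stimuli_enabled
    rt.stimuli_enabled = False
    try:
        st = state.copy()
        elapsed = 0.0
        chunk = min(0.1, relax_max)
        while True:
            dvdt = rt.derivative(st.t, st)[:rt.nc]
            if np.max(np.abs(dvdt)) < dvdt_tol:
                break
            if elapsed >= relax_max:
                logger.warning(
                    "relaxation hit the %.3g s cap with max|dV/dt| = %.3g mV/s",
                    relax_max, float(np.max(np.abs(dvdt))))
                break
            h = min(chunk, relax_max - elapsed)
            if method in ("forward_euler", "semi_implicit_cn"):
                st, *_ = integrate_fixed(rt, st, st.t + h, dt, method,
                                         record_stride=10 ** 9)
            else:
                st, *_ = integrate_adaptive(rt, st, st.t + h, abstol, reltol)
            elapsed += h
        st.t = 0.0
        return st, elapsed
    finally:
        rt.stimuli_enabled = saved


# ---------------------------------------------------------------------------
# Convergence studies
# ---------------------------------------------------------------------------

def convergence_slope(problem: str, method: str, dts) -> float:
    """Least-squares slope of log10(RMSE) vs log10(dt) on a registered
    test problem with a known exact solution.

    Requires at least 4 step sizes spanning at least two decades.
    """
    from .fixtures import get_problem  # local import avoids a cycle

    dts = np.asarray(sorted(dts, reverse=True), dtype=float)
    if dts.size < 4:
        raise ValueError("need at least 4 step sizes")
    if dts.max() / dts.min() < 100:
        raise ValueError("step sizes must span at least two decades")
    prob = get_problem(problem)
    rmses = []
    for dt in dts:
        rmses.append(problem_rmse(prob, method, dt))
    rmses = np.asarray(rmses)
    if np.any(rmses == 0):
        raise ValueError(
            "degenerate RMSE (exact to round-off); no convergence slope")
    slope = np.polyfit(np.log10(dts), np.log10(rmses), 1)[0]
    return float(slope)


def problem_rmse(prob, method: str, dt: float) -> float:
    """RMSE of one fixed-step run against the problem's exact solution."""
    rt = RuntimeNetwork(prob.spec)
    st = rt.initial_state(default_V=prob.V0)
    if method == "exact":
        return 0.0
    if method not in ("forward_euler", "semi_implicit_cn"):
        raise ValueError(f"unknown method '{method}' for convergence study")
    _, times, snaps, _, _ = integrate_fixed(rt, st, prob.t_end, dt, method)
    V = snaps[:, 0]
    exact = prob.exact(times)
    return float(np.sqrt(np.mean((V - exact) ** 2)))
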