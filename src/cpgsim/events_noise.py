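"""Point events and balanced Poisson background noise.

Each noise target receives two independent Poisson-driven exponential-decay
conductances, an inhibitory one (reversal E_i = −90 mV by default) and an
excitatory one (E_e = +60 mV):

    dg/dt = −g/τ + w·Σ_j δ(t − T_j),     I = g_i(V−E_i) + g_e(V−E_e)

The user fixes the inhibitory weight w_i; the excitatory weight is derived so
the mean driving currents cancel at the resting potential V_r:

    w_e = w_i · |λ_i τ_i (E_i − V_r)| / (λ_e τ_e |E_e − V_r|)

so that w_e λ_e τ_e (E_e − V_r) + w_i λ_i τ_i (E_i − V_r) = 0 (Campbell's
theorem gives mean conductance w·λ·τ for a Poisson shot-noise process).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .schema_io import NetworkValueError, NoiseTargetSpec

__all__ = [
    "EventTrain",
    "NoiseRealization",
    "detect_spikes",
    "poisson_train",
    "balanced_weight",
    "noise_state_update",
    "noise_current",
    "measure_bias",
    "spawn_noise_trains",
]


@dataclass(frozen=True)
class EventTrain:
    """Timestamped point events from one source (strictly increasing, s)."""

    source: str
    times: np.ndarray
    kind: str = "spike"  # spike | poisson_e | poisson_i

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise NetworkValueError(
                f"event train '{self.source}': times must be strictly "
                "increasing and non-negative")

    def __len__(self):
        return self.times.size


@dataclass
class NoiseRealization:
    """Realised noise input for one target: the two event trains, the derived
    excitatory weight, and the resting potential it was balanced against."""

    target: str
    train_i: EventTrain
    train_e: EventTrain
    w_e: float
    V_r: float


def detect_spikes(time, V, threshold: float = 0.0,
                  refractory: float = 2e-3, source: str = "") -> EventTrain:
    """One event per upward threshold crossing of a sampled voltage trace.

    Crossing times are linearly interpolated; crossings closer than
    ``refractory`` (default 2 ms) to the previous event are merged so a
    single chattering spike yields one event.
    """
    time = np.asarray(time, dtype=float)
    V = np.asarray(V, dtype=float)
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return EventTrain(source, np.empty(0), "spike")
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    t_cross = time[idx] + frac * (time[idx + 1] - time[idx])
    kept = [t_cross[0]]
    for t in t_cross[1:]:
        if t - kept[-1] > refractory:
            kept.append(t)
    return EventTrain(source, np.array(kept), "spike")


def poisson_train(rate: float, duration: float, seed,
                  source: str = "", kind: str = "spike") -> EventTrain:
    """Homogeneous Poisson process on [0, duration) at ``rate`` Hz.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    if rate < 0 or duration < 0:
        raise NetworkValueError("rate and duration must be >= 0")
    rng = np.random.default_rng(seed)
    if rate == 0 or duration == 0:
        return EventTrain(source, np.empty(0), kind)
    # draw exponential ISIs in blocks until past the horizon
    times = []
    t = 0.0
    block = max(16, int(rate * duration * 1.2) + 16)
    while t < duration:
        isis = rng.exponential(1.0 / rate, size=block)
        cum = t + np.cumsum(isis)
        times.append(cum[cum < duration])
        t = cum[-1]
    times = np.concatenate(times) if times else np.empty(0)
    return EventTrain(source, times, kind)


def balanced_weight(w_i: float, lambda_i: float, lambda_e: float,
                    tau_i: float, tau_e: float,
                    E_i: float, E_e: float, V_r: float) -> float:
    """Excitatory weight balancing the mean noise currents at V_r (µS)."""
    if lambda_e <= 0 or lambda_i < 0 or tau_i <= 0 or tau_e <= 0:
        raise NetworkValueError("noise rates and time constants must be positive")
    if V_r == E_i:
        raise NetworkValueError("resting potential equals E_i; balance undefined")
    if V_r == E_e:
        raise NetworkValueError("resting potential equals E_e; balance undefined")
    return w_i * abs(lambda_i * tau_i * (E_i - V_r)) / (
        lambda_e * tau_e * abs(E_e - V_r))


def noise_state_update(g: float, tau: float, dt: float,
                       n_events: int, w: float) -> float:
    """Advance one noise conductance across a step: exact exponential decay
    with time constant ``tau`` plus an increment ``w`` per event in the step."""
    return g * np.exp(-dt / tau) + w * n_events


def noise_current(V, g_i, g_e, E_i: float = -90.0, E_e: float = 60.0):
    """I(noise) = g_i·(V−E_i) + g_e·(V−E_e), nA."""
    return g_i * (V - E_i) + g_e * (V - E_e)


def spawn_noise_trains(noise_specs: tuple[NoiseTargetSpec, ...],
                       duration: float, master_seed: int,
                       V_r_by_target: dict[str, float]) -> list[NoiseRealization]:
    """Build per-target balanced noise realizations from one master seed.

    Each target gets its own deterministic substreams (one per kind), so
    different targets' trains are statistically independent.
    """
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(len(noise_specs))
    out = []
    for nt, child in zip(noise_specs, children):
        if nt.seed is not None:
            child = np.random.SeedSequence(nt.seed)
        ss_i, ss_e = child.spawn(2)
        V_r = V_r_by_target[nt.target]
        w_e = balanced_weight(nt.w_i, nt.rate_i, nt.rate_e,
                              nt.tau_i, nt.tau_e, nt.E_i, nt.E_e, V_r)
        out.append(NoiseRealization(
            target=nt.target,
            train_i=poisson_train(nt.rate_i, duration, ss_i, nt.target, "poisson_i"),
            train_e=poisson_train(nt.rate_e, duration, ss_e, nt.target, "poisson_e"),
            w_e=w_e, V_r=V_r))
    return out


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def gaussian_fit_mean(samples: np.ndarray) -> float:
    """Mean of a least-squares Gaussian fit to a Freedman–Diaconis histogram."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1000:
        raise NetworkValueError("need at least 1000 samples for a stable fit")
    if np.ptp(samples) == 0:
        return float(samples[0])
    counts, edges = np.histogram(samples, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(samples.mean()), float(samples.std()) or 1.0)
    try:
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10000)
        return float(popt[1])
    except RuntimeError:
        return float(samples.mean())


def measure_bias(trace_with_noise, trace_noiseless,
                 comp: str) -> tuple[float, float]:
    """Noise bias of a run relative to its noiseless twin.

    Returns ``(voltage_bias, current_bias)``: the mean of a Gaussian fit to
    the noisy voltage histogram minus the noiseless resting potential (mV),
    and the time average of the recorded noise current (nA).
    """
    Vn = np.asarray(trace_with_noise.data[(comp, "V")])
    V0 = np.asarray(trace_noiseless.data[(comp, "V")])
    key = (comp, "I_noise")
    if key in trace_with_noise.data:
        current_bias = float(np.mean(trace_with_noise.data[key]))
    else:
        current_bias = 0.0
    rest = float(V0[-1])
    if np.ptp(Vn) == 0:  # zero-weight noise: runs coincide exactly
        return float(Vn[-1] - rest), current_bias
    return gaussian_fit_mean(Vn) - rest, current_bias
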