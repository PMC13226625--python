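"""Spike detection, Poisson sources, balanced-noise weights and updates."""

import math

import numpy as np
import pytest
from scipy import stats

from cpgsim import (
    NetworkValueError,
    NoiseTargetSpec,
    balanced_weight,
    detect_spikes,
    noise_current,
    noise_state_update,
    poisson_train,
    spawn_noise_trains,
)
from cpgsim.events_noise import EventTrain


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def test_single_ramp_crossing_interpolated():
    t = np.array([0.0, 1.0, 2.0])
    V = np.array([-70.0, -70.0, 20.0])
    train = detect_spikes(t, V)
    assert len(train) == 1
    # linear interpolation between (1, −70) and (2, 20): crossing at 1 + 70/90
    assert train.times[0] == pytest.approx(1.0 + 70.0 / 90.0)


def test_constant_trace_no_events():
    t = np.linspace(0, 1, 100)
    assert len(detect_spikes(t, np.full(100, -70.0))) == 0


def test_chatter_merges_to_one_event():
    t = np.linspace(0, 1e-3, 101)
    V = np.where(np.arange(101) % 2 == 0, -1.0, 1.0)  # ±1 mV wobble in 1 ms
    assert len(detect_spikes(t, V)) == 1


def test_event_train_invariants():
    with pytest.raises(NetworkValueError):
        EventTrain("x", np.array([0.2, 0.1]))
    with pytest.raises(NetworkValueError):
        EventTrain("x", np.array([-0.1, 0.2]))


# ---------------------------------------------------------------------------
# Poisson trains
# ---------------------------------------------------------------------------

def test_poisson_degenerate_cases():
    assert len(poisson_train(0.0, 10.0, 1)) == 0
    assert len(poisson_train(50.0, 0.0, 1)) == 0


def test_poisson_mean_count():
    """Counts over 100 seeds stay within 3σ of rate·duration."""
    rate, duration = 50.0, 50.0
    counts = [len(poisson_train(rate, duration, seed)) for seed in range(100)]
    expected = rate * duration
    sigma = math.sqrt(expected / 100)  # sd of the mean of 100 Poisson counts
    assert abs(np.mean(counts) - expected) < 3 * sigma


def test_poisson_isi_distribution():
    """ISIs pass a KS test against Exp(rate) at α = 0.01."""
    train = poisson_train(50.0, 200.0, 7)
    isis = np.diff(train.times)
    _, p = stats.kstest(isis, "expon", args=(0, 1 / 50.0))
    assert p > 0.01


def test_poisson_reproducible_per_seed():
    a = poisson_train(20.0, 5.0, 99)
    b = poisson_train(20.0, 5.0, 99)
    assert np.array_equal(a.times, b.times)


# ---------------------------------------------------------------------------
# balanced weights
# ---------------------------------------------------------------------------

def test_balanced_weight_example():
    """λe=λi, τe=τi, Ei=−90, Ee=60, Vr=−60 → w_e = w_i·|30/120| = w_i/4,
    which zeroes the summed mean driving currents."""
    w_i = 1e-5
    w_e = balanced_weight(w_i, 50.0, 50.0, 0.025, 0.025, -90.0, 60.0, -60.0)
    assert w_e == pytest.approx(0.25 * w_i)
    lam, tau = 50.0, 0.025
    mean_I = (w_i * lam * tau * (-90.0 - -60.0)
              + w_e * lam * tau * (60.0 - -60.0))
    assert mean_I == pytest.approx(0.0, abs=1e-18)


def test_balanced_weight_symmetry_point():
    # V_r equidistant from both reversals ⇒ equal weights
    w_e = balanced_weight(2e-5, 50.0, 50.0, 0.025, 0.025, -90.0, 60.0, -15.0)
    assert w_e == pytest.approx(2e-5)


def test_balanced_weight_rate_proportionality():
    base = balanced_weight(1e-5, 50.0, 50.0, 0.025, 0.025, -90.0, 60.0, -60.0)
    doubled = balanced_weight(1e-5, 50.0, 100.0, 0.025, 0.025, -90.0, 60.0, -60.0)
    assert doubled == pytest.approx(base / 2)


def test_balanced_weight_degenerate_rest():
    with pytest.raises(NetworkValueError):
        balanced_weight(1e-5, 50.0, 50.0, 0.025, 0.025, -90.0, 60.0, -90.0)


# ---------------------------------------------------------------------------
# conductance updates and currents
# ---------------------------------------------------------------------------

def test_noise_state_decay_and_jump():
    g = noise_state_update(1.0, 0.025, 0.025, 0, 1e-5)  # one time constant
    assert g == pytest.approx(1.0 / math.e)
    g = noise_state_update(0.0, 0.025, 1e-9, 1, 3e-5)
    assert g == pytest.approx(3e-5, rel=1e-6)  # jump by exactly w


def test_noise_state_longrun_mean_campbell():
    """Long-run mean of g under Poisson drive is w·λ·τ (shot-noise mean)."""
    rate, tau, w, dt, T = 200.0, 0.02, 1e-5, 1e-3, 500.0
    train = poisson_train(rate, T, 3)
    times = train.times
    g, acc, p = 0.0, 0.0, 0
    n = int(T / dt)
    for i in range(n):
        hi = (i + 1) * dt
        k = 0
        while p < times.size and times[p] <= hi:
            p += 1
            k += 1
        g = noise_state_update(g, tau, dt, k, w)
        acc += g
    mean = acc / n
    expected = w * rate * tau
    # variance of the time average: Var(g)·2τ/T with Var(g) = w²λτ/2
    se = math.sqrt(w ** 2 * rate * tau / 2 * 2 * tau / T)
    assert abs(mean - expected) < 3 * se + w  # + w for discretisation offset


def test_spike_count_invariant_to_sampling_rate():
    """Counts from a spiky trace agree at any sampling above 2 kHz."""
    spike_times = np.array([0.11, 0.27, 0.40, 0.63, 0.88])

    def sample(rate):
        t = np.arange(0.0, 1.0, 1.0 / rate)
        V = np.full_like(t, -65.0)
        for s in spike_times:  # 3 ms triangular spikes peaking at +20 mV
            V = np.maximum(V, 20.0 - 85.0 / 1.5e-3 * np.abs(t - s))
        return t, V

    counts = []
    for rate in (2000, 5000, 20000):
        t, V = sample(rate)
        counts.append(len(detect_spikes(t, V)))
    assert counts == [5, 5, 5]


def test_measure_bias_zero_weight_exact():
    """Zero-weight noise: bias is exactly (0, 0) against the noiseless twin."""
    from cpgsim import measure_bias
    from cpgsim.runner import TraceSet

    t = np.linspace(0, 10, 5000)
    V = np.full_like(t, -60.0)
    noisy = TraceSet(time=t, data={("P", "V"): V.copy(),
                                   ("P", "I_noise"): np.zeros_like(t)},
                     manifest={})
    quiet = TraceSet(time=t, data={("P", "V"): V.copy()}, manifest={})
    vb, ib = measure_bias(noisy, quiet, "P")
    assert vb == 0.0 and ib == 0.0


def test_noise_current_substitutions():
    assert noise_current(-60.0, 0.0, 0.0) == 0.0
    assert noise_current(60.0, 1e-5, 2e-5) == pytest.approx(1e-5 * 150.0)
    assert noise_current(-60.0, 1e-5, 0.0) == pytest.approx(3e-4)


# ---------------------------------------------------------------------------
# master-seed scheme
# ---------------------------------------------------------------------------

def _two_target_realizations(seed):
    specs = (
        NoiseTargetSpec("a", rate_i=50.0, rate_e=50.0, w_i=1e-5,
                        tau_i=0.025, tau_e=0.025),
        NoiseTargetSpec("b", rate_i=50.0, rate_e=50.0, w_i=1e-5,
                        tau_i=0.025, tau_e=0.025),
    )
    return spawn_noise_trains(specs, 200.0, seed,
                              {"a": -60.0, "b": -60.0})


def test_spawned_trains_deterministic_and_distinct():
    r1 = _two_target_realizations(42)
    r2 = _two_target_realizations(42)
    assert np.array_equal(r1[0].train_i.times, r2[0].train_i.times)
    assert not np.array_equal(r1[0].train_i.times[:50], r1[1].train_i.times[:50])
    assert r1[0].w_e == pytest.approx(0.25e-5)


def test_independent_targets_uncorrelated_counts():
    """Binned counts of different targets' trains are uncorrelated."""
    r = _two_target_realizations(7)
    bins = np.arange(0, 200.0 + 1, 1.0)
    ca, _ = np.histogram(r[0].train_i.times, bins)
    cb, _ = np.histogram(r[1].train_i.times, bins)
    rho = np.corrcoef(ca, cb)[0, 1]
    assert abs(rho) < 3.0 / math.sqrt(len(ca))
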