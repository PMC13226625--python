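"""Burst grouping, phase-duration statistics, objective, grid search."""

import math

import numpy as np
import pytest

from cpgsim import (
    NetworkValueError,
    detect_bursts,
    grid_search,
    make_fixture,
    objective,
    phase_durations,
    synthetic_bursts,
)
from cpgsim.analysis import SENTINEL, PhaseSummary


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------

def test_two_bursts_from_gapped_spikes():
    spikes = np.array([0.1, 0.2, 0.3, 3.0, 3.1, 3.2])
    bursts = detect_bursts(spikes, max_isi=1.0, min_spikes=2)
    assert len(bursts) == 2
    assert bursts[0].duration == pytest.approx(0.2)
    assert bursts[1].duration == pytest.approx(0.2)
    assert bursts[0].count == 3


def test_empty_and_subthreshold_trains():
    assert detect_bursts(np.array([]), 1.0, 2) == []
    assert detect_bursts(np.array([1.0]), 1.0, 2) == []


# ---------------------------------------------------------------------------
# phase durations
# ---------------------------------------------------------------------------

def test_exact_recovery_with_first_pattern_excluded():
    pro, ret = synthetic_bursts(4.0, 6.0, n_patterns=5, isi=0.05, seed=0)
    s = phase_durations(detect_bursts(pro, 0.5, 3), detect_bursts(ret, 0.5, 3))
    assert s.n_patterns == 4
    assert s.protraction_mean == pytest.approx(4.0, abs=1e-9)
    assert s.retraction_mean == pytest.approx(6.0, abs=1e-9)
    assert s.protraction_sd == pytest.approx(0.0, abs=1e-9)


def test_single_pattern_yields_empty_summary():
    pro, ret = synthetic_bursts(4.0, 6.0, n_patterns=1, seed=0)
    s = phase_durations(detect_bursts(pro, 0.5, 3), detect_bursts(ret, 0.5, 3))
    assert s.empty


def test_jittered_durations_recovered_within_3_sem():
    pro, ret = synthetic_bursts(4.0, 6.0, n_patterns=30, isi=0.05,
                                jitter_sd=0.1, seed=3)
    s = phase_durations(detect_bursts(pro, 0.5, 3), detect_bursts(ret, 0.5, 3))
    assert abs(s.protraction_mean - 4.0) < 3 * s.protraction_sem + 0.05
    assert abs(s.retraction_mean - 6.0) < 3 * s.retraction_sem + 0.05
    # sampling distribution of the SD: sd_hat ~ 0.1 within 3×0.1/√(2n)
    assert abs(s.protraction_sd - 0.1) < 3 * 0.1 / math.sqrt(2 * s.n_patterns) + 0.02


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def test_objective_values_and_sentinel():
    s = PhaseSummary(protraction_mean=4.0, retraction_mean=6.0, n_patterns=3)
    assert objective(s, 4.0, 6.0) == 0.0
    assert objective(s, 4.0, 5.0) == pytest.approx(1.0)
    assert objective(PhaseSummary(), 4.0, 6.0) == SENTINEL


# ---------------------------------------------------------------------------
# grid search (mock backends)
# ---------------------------------------------------------------------------

class QuadraticMock:
    """Backend whose objective is (x−a)² + (y−b)² via the phase means."""

    def __init__(self, a, b):
        self.a, self.b = a, b

    def __call__(self, spec, seed):
        x = spec.neurons[0].compartments[0].channels[0].gbar
        y = spec.neurons[0].compartments[0].Cm
        return PhaseSummary(protraction_mean=x, retraction_mean=y,
                            n_patterns=3)


class FailingMock(QuadraticMock):
    def __call__(self, spec, seed):
        if abs(spec.neurons[0].compartments[0].channels[0].gbar - 0.3) < 1e-12:
            raise RuntimeError("simulated blow-up")
        return super().__call__(spec, seed)


MESH1 = np.linspace(0.1, 0.5, 3)   # sweeps the leak gbar
MESH2 = np.linspace(0.5, 1.5, 3)   # sweeps Cm
P1 = ("Channels:1:gbar", MESH1)
P2 = ("Neurons:1:Cm", MESH2)


def test_argmin_matches_exhaustive_oracle(leaky_problem):
    res = grid_search(leaky_problem.spec, P1, P2, targets=(0.3, 1.0),
                      backend=QuadraticMock(0.3, 1.0))
    # brute-force oracle over all 9 cells
    brute = np.array([[(x - 0.3) ** 2 + (y - 1.0) ** 2
                       for y in MESH2] for x in MESH1])
    np.testing.assert_allclose(res.objective, brute, atol=1e-12)
    assert res.argmin == tuple(np.unravel_index(brute.argmin(), brute.shape))
    assert res.best_params == pytest.approx((0.3, 1.0))


def test_single_cell_mesh(leaky_problem):
    res = grid_search(leaky_problem.spec, ("Channels:1:gbar", [0.2]),
                      ("Neurons:1:Cm", [1.0]), targets=(0.0, 0.0),
                      backend=QuadraticMock(0, 0))
    assert res.argmin == (0, 0)
    assert res.objective.shape == (1, 1)


def test_tie_breaks_to_lowest_index_pair(leaky_problem):
    class Flat(QuadraticMock):
        def __call__(self, spec, seed):
            return PhaseSummary(protraction_mean=1.0, retraction_mean=1.0,
                                n_patterns=3)

    res = grid_search(leaky_problem.spec, P1, P2, targets=(1.0, 1.0),
                      backend=Flat(0, 0))
    assert res.argmin == (0, 0)


def test_parallel_equals_serial_bitwise(leaky_problem):
    kw = dict(targets=(0.3, 1.0), backend=QuadraticMock(0.3, 1.0))
    serial = grid_search(leaky_problem.spec, P1, P2, batch_size=1, **kw)
    parallel = grid_search(leaky_problem.spec, P1, P2, batch_size=3, **kw)
    assert np.array_equal(serial.objective, parallel.objective)
    assert serial.argmin == parallel.argmin


def test_failed_cell_gets_sentinel_and_sweep_continues(leaky_problem):
    res = grid_search(leaky_problem.spec, P1, P2, targets=(0.1, 0.5),
                      backend=FailingMock(0.1, 0.5))
    assert np.isinf(res.objective[1, :]).all()   # gbar = 0.3 row failed
    assert np.isfinite(res.objective[0, :]).all()
    assert res.argmin == (0, 0)


def test_argmin_invariant_under_monotone_transform(leaky_problem):
    res = grid_search(leaky_problem.spec, P1, P2, targets=(0.32, 0.9),
                      backend=QuadraticMock(0.3, 1.0))
    root = np.sqrt(res.objective)
    assert res.argmin == tuple(np.unravel_index(root.argmin(), root.shape))


def test_empty_mesh_rejected(leaky_problem):
    with pytest.raises(NetworkValueError):
        grid_search(leaky_problem.spec, ("Channels:1:gbar", []), P2,
                    targets=(0, 0), backend=QuadraticMock(0, 0))
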