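"""Motor-pattern analysis and the two-parameter grid search.

A motor pattern is a protraction-phase burst followed by the next
retraction-phase burst; phases are defined by spiking activity in designated
cells.  Bursts are maximal runs of spikes whose consecutive inter-spike
intervals stay below ``max_isi``; phase duration is first-to-last spike of
the burst.  The first pattern of a run is excluded from the summary so
transients do not contaminate the statistics.  The sweep minimises

    (mean_P − target_P)² + (mean_R − target_R)²

over a rectangular parameter mesh, each cell one independent simulation.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np

from .events_noise import EventTrain, detect_spikes
from .schema_io import NetworkSpec, NetworkValueError, set_workbook_value

logger = logging.getLogger("cpgsim")

__all__ = [
    "Burst",
    "PhaseSummary",
    "SweepResult",
    "detect_bursts",
    "phase_durations",
    "objective",
    "grid_search",
    "SimulationBackend",
    "SENTINEL",
]

SENTINEL = math.inf  # objective value for failed or pattern-less simulations


@dataclass(frozen=True)
class Burst:
    onset: float
    offset: float
    count: int
    source: str = ""

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PhaseSummary:
    """Per-phase duration statistics over the retained motor patterns."""

    protraction_mean: float = math.nan
    protraction_sd: float = math.nan
    protraction_sem: float = math.nan
    retraction_mean: float = math.nan
    retraction_sd: float = math.nan
    retraction_sem: float = math.nan
    n_patterns: int = 0

    @property
    def empty(self) -> bool:
        return self.n_patterns < 1


@dataclass
class SweepResult:
    axis1: np.ndarray
    axis2: np.ndarray
    protraction: np.ndarray  # (len(axis1), len(axis2)) mean durations, s
    retraction: np.ndarray
    objective: np.ndarray
    argmin: tuple[int, int]
    best_params: tuple[float, float]
    param1: str = ""
    param2: str = ""


def detect_bursts(spikes, max_isi: float, min_spikes: int,
                  source: str = "") -> list[Burst]:
    """Group sorted spike times into bursts.

    A burst is a maximal run with consecutive ISIs <= ``max_isi`` containing
    at least ``min_spikes`` spikes; onset/offset are its first/last spike.
    """
    times = spikes.times if isinstance(spikes, EventTrain) else np.asarray(spikes)
    if times.size == 0:
        return []
    src = source or (spikes.source if isinstance(spikes, EventTrain) else "")
    breaks = np.nonzero(np.diff(times) > max_isi)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [times.size - 1]])
    out = []
    for a, b in zip(starts, ends):
        n = b - a + 1
        if n >= min_spikes:
            out.append(Burst(onset=float(times[a]), offset=float(times[b]),
                             count=int(n), source=src))
    return out


def phase_durations(protraction_bursts, retraction_bursts) -> PhaseSummary:
    """Pair protraction bursts with the next retraction burst and summarise.

    A retraction burst belongs to the most recent preceding protraction
    burst; an unpaired protraction burst at the tail is dropped with a
    warning.  The first complete pattern is excluded; mean/SD/SEM are over
    the remainder.
    """
    pro = sorted(protraction_bursts, key=lambda b: b.onset)
    ret = sorted(retraction_bursts, key=lambda b: b.onset)
    pairs = []
    ri = 0
    for k, p in enumerate(pro):
        nxt = pro[k + 1].onset if k + 1 < len(pro) else math.inf
        while ri < len(ret) and ret[ri].onset < p.onset:
            ri += 1
        if ri < len(ret) and ret[ri].onset < nxt:
            pairs.append((p, ret[ri]))
            ri += 1
        elif k == len(pro) - 1:
            logger.warning("unpaired protraction burst at t = %.3g s dropped", p.onset)
    pairs = pairs[1:]  # exclude the first motor pattern
    if not pairs:
        return PhaseSummary()
    pd_ = np.array([p.duration for p, _ in pairs])
    rd = np.array([r.duration for _, r in pairs])
    n = len(pairs)
    sdP = float(pd_.std(ddof=1)) if n > 1 else 0.0
    sdR = float(rd.std(ddof=1)) if n > 1 else 0.0
    return PhaseSummary(
        protraction_mean=float(pd_.mean()), protraction_sd=sdP,
        protraction_sem=sdP / math.sqrt(n),
        retraction_mean=float(rd.mean()), retraction_sd=sdR,
        retraction_sem=sdR / math.sqrt(n),
        n_patterns=n)


def objective(summary: PhaseSummary, target_protraction: float,
              target_retraction: float) -> float:
    """Squared phase-duration error, s²; +inf sentinel for empty summaries."""
    if summary.empty:
        logger.warning("empty phase summary: objective set to sentinel")
        return SENTINEL
    return ((summary.protraction_mean - target_protraction) ** 2
            + (summary.retraction_mean - target_retraction) ** 2)


@dataclass
class SimulationBackend:
    """Picklable sweep backend: run a full simulation, extract the phases."""

    protraction_cell: str
    retraction_cell: str
    max_isi: float = 0.5
    min_spikes: int = 3
    threshold: float = 0.0

    def __call__(self, spec: NetworkSpec, seed: int) -> PhaseSummary:
        from .runner import run_simulation

        traces, _ = run_simulation(spec, seed=seed)

        def bursts(cell):
            key = (cell, "V")
            if key not in traces.data:
                raise NetworkValueError(f"phase cell '{cell}' not recorded")
            tr = detect_spikes(traces.time, traces.data[key],
                               threshold=self.threshold, source=cell)
            return detect_bursts(tr, self.max_isi, self.min_spikes, source=cell)

        return phase_durations(bursts(self.protraction_cell),
                               bursts(self.retraction_cell))


def _sweep_cell(args):
    spec, addr1, v1, addr2, v2, seed, backend = args
    try:
        s = set_workbook_value(spec, addr1, v1)
        s = set_workbook_value(s, addr2, v2)
        summary = backend(s, seed)
        return (summary.protraction_mean, summary.retraction_mean, summary)
    except Exception as exc:
        logger.warning("sweep cell (%s=%.4g, %s=%.4g) failed: %s",
                       addr1, v1, addr2, v2, exc)
        return None


def grid_search(spec: NetworkSpec, param1, param2, targets,
                batch_size: int = 1, backend=None, seed: int = 0,
                protraction_cell: str | None = None,
                retraction_cell: str | None = None,
                max_isi: float = 0.5, min_spikes: int = 3) -> SweepResult:
    """Exhaustive two-parameter sweep against target phase durations.

    ``param1``/``param2`` are ``(workbook_address, mesh)`` pairs where the
    address is ``Sheet:row:column``; ``targets`` is
    ``(target_protraction, target_retraction)`` in seconds.  Each mesh cell
    runs one simulation with a deterministic per-cell seed
    (``seed + flat_index``); results are identical regardless of
    ``batch_size``.  Ties in the objective resolve to the lowest index pair.
    """
    addr1, mesh1 = param1
    addr2, mesh2 = param2
    mesh1 = np.asarray(mesh1, dtype=float)
    mesh2 = np.asarray(mesh2, dtype=float)
    if mesh1.size == 0 or mesh2.size == 0:
        raise NetworkValueError("parameter meshes must be nonempty")
    if backend is None:
        if protraction_cell is None or retraction_cell is None:
            raise NetworkValueError(
                "default backend needs protraction_cell and retraction_cell")
        backend = SimulationBackend(protraction_cell, retraction_cell,
                                    max_isi=max_isi, min_spikes=min_spikes)
    n1, n2 = mesh1.size, mesh2.size
    target_p, target_r = targets

    jobs = []
    for i, v1 in enumerate(mesh1):
        for j, v2 in enumerate(mesh2):
            jobs.append((spec, addr1, float(v1), addr2, float(v2),
                         seed + i * n2 + j, backend))
    if batch_size > 1:
        with ProcessPoolExecutor(max_workers=batch_size) as pool:
            results = list(pool.map(_sweep_cell, jobs))
    else:
        results = [_sweep_cell(j) for j in jobs]

    pro = np.full((n1, n2), math.nan)
    ret = np.full((n1, n2), math.nan)
    obj = np.full((n1, n2), SENTINEL)
    for k, res in enumerate(results):
        i, j = divmod(k, n2)
        if res is None:
            continue
        pmean, rmean, summary = res
        pro[i, j] = pmean
        ret[i, j] = rmean
        obj[i, j] = objective(summary, target_p, target_r)
    flat = int(np.argmin(obj))  # C order: ties resolve to lowest (i, j)
    argmin = (flat // n2, flat % n2)
    return SweepResult(
        axis1=mesh1, axis2=mesh2, protraction=pro, retraction=ret,
        objective=obj, argmin=argmin,
        best_params=(float(mesh1[argmin[0]]), float(mesh2[argmin[1]])),
        param1=addr1, param2=addr2)
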