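"""Batch data transformation, dynamic feedback scheduling, and pipeline drivers.

Large spectrum sets are processed by a two-level worker hierarchy
emulated portably: *worker groups* pull chunks of work from a manager,
and inside each worker a loader role prefetches the next chunk while the
current one computes (double buffering). The batching pipeline is

    sort by length -> concatenate into near-equal groups -> chunk
    -> probe -> feedback-factor allocation -> execute -> reassemble

Sorting ascending by peak count and greedily concatenating spectra into
groups no longer than the longest single spectrum makes work units of
near-equal size; a short seeded probe measures each worker's utilization
and queue backlog, from which a feedback regulatory factor decides how
many chunks each worker receives. The contract that matters is that
:func:`run_parallel` returns, for every input spectrum, the *identical*
PSM that :func:`run_serial` would — scheduling only changes who computes
what, never the result.

Two pools are provided: :class:`ThreadPool` executes chunks on real
threads with wall-clock instrumentation, and :class:`SimulatedPool` is a
deterministic discrete-event model of heterogeneous worker speeds used
for scheduler experiments.
"""

from __future__ import annotations

import logging
import queue
import threading
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import RunConfig
from .graph_core import build_graph, enumerate_candidates, extract_tags
from .scoring import PSM, score_candidates
from .spectra_io import Spectrum, effective_peaks

__all__ = [
    "SpectrumGroup",
    "Chunk",
    "WorkerFeedback",
    "Allocation",
    "WorkerStats",
    "ThreadPool",
    "SimulatedPool",
    "sort_spectra",
    "concatenate_groups",
    "make_chunks",
    "probe",
    "feedback_from_stats",
    "sample_probe_chunks",
    "regulatory_factor",
    "allocate",
    "load_imbalance_percent",
    "process_spectrum",
    "run_serial",
    "run_parallel",
    "bench_scheduler",
]

log = logging.getLogger(__name__)

#: In-memory sentinel separating concatenated spectra within a group when a
#: group is serialized into a flat work buffer.
GROUP_TERMINATOR = object()


# ---------------------------------------------------------------------------
# data transformation: sort -> concatenate -> chunk


@dataclass
class SpectrumGroup:
    """Consecutive length-sorted spectra concatenated into one work unit."""

    members: list[Spectrum]

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.members)

    def serialize(self) -> list:
        """Flat member layout with terminator sentinels between spectra."""
        out: list = []
        for i, s in enumerate(self.members):
            if i:
                out.append(GROUP_TERMINATOR)
            out.append(s)
        return out


@dataclass
class Chunk:
    """The scheduling unit: a consecutive run of spectrum groups."""

    groups: list[SpectrumGroup]
    chunk_id: int

    @property
    def total_length(self) -> int:
        return sum(g.total_length for g in self.groups)

    def spectra(self) -> list[Spectrum]:
        return [s for g in self.groups for s in g.members]


@dataclass
class WorkerFeedback:
    """Probe measurements for one worker, plus its normalized factor."""

    worker_id: int
    utilization: float        # busy fraction of the probe wall span, in [0, 1]
    mean_queue_length: float  # time-averaged count of tasks waiting (not running)
    regulatory_factor: float = 0.0


@dataclass
class Allocation:
    """A complete assignment of chunks to workers."""

    assignment: dict[int, int]          # chunk_id -> worker_id
    loads: list[float]                  # per-worker summed total_length
    per_worker: list[list[int]]         # chunk ids per worker, ascending

    @property
    def imbalance_percent(self) -> float:
        return load_imbalance_percent(self.loads)


def load_imbalance_percent(loads: Sequence[float]) -> float:
    """(max load − mean load) / mean load × 100; 0 for an all-zero load set."""
    loads = np.asarray(loads, dtype=float)
    mean = loads.mean()
    if mean == 0:
        return 0.0
    return float((loads.max() - mean) / mean * 100.0)


def sort_spectra(spectra: Sequence[Spectrum]) -> list[Spectrum]:
    """Ascending by peak count, ties broken by id; stable."""
    return sorted(spectra, key=lambda s: (s.length, s.id))


def concatenate_groups(sorted_spectra: Sequence[Spectrum]) -> list[SpectrumGroup]:
    """Greedy left-to-right packing into groups bounded by the longest spectrum.

    The target group size is the largest single peak count, so every group
    total stays at or below it (a lone over-long spectrum would be a
    singleton by construction). Input must already be length-sorted.
    """
    if not sorted_spectra:
        return []
    target = max(s.length for s in sorted_spectra)
    groups: list[SpectrumGroup] = []
    current: list[Spectrum] = []
    current_total = 0
    for s in sorted_spectra:
        if current and current_total + s.length > target:
            groups.append(SpectrumGroup(current))
            current, current_total = [], 0
        current.append(s)
        current_total += s.length
    groups.append(SpectrumGroup(current))
    return groups


def make_chunks(
    groups: Sequence[SpectrumGroup], n_workers: int, groups_per_chunk: int
) -> list[Chunk]:
    """Pack consecutive groups into chunks, reshaping toward a worker multiple.

    Groups are taken ``groups_per_chunk`` at a time; if the resulting chunk
    count is not a multiple of ``n_workers``, trailing multi-group chunks
    are split (one group moved out at a time, scanning from the end) until
    it is — or until no chunk can be split without emptying it.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if groups_per_chunk < 1:
        raise ValueError("groups_per_chunk must be >= 1")
    if not groups:
        return []
    parts: list[list[SpectrumGroup]] = [
        list(groups[i : i + groups_per_chunk]) for i in range(0, len(groups), groups_per_chunk)
    ]
    while len(parts) % n_workers != 0:
        for i in range(len(parts) - 1, -1, -1):
            if len(parts[i]) >= 2:
                moved = parts[i].pop()
                parts.insert(i + 1, [moved])
                break
        else:
            break  # nothing splittable left; keep the count we have
    return [Chunk(p, i) for i, p in enumerate(parts)]


# ---------------------------------------------------------------------------
# worker pools


@dataclass
class WorkerStats:
    """Per-worker timing collected while executing an assignment."""

    worker_id: int
    busy_time: float = 0.0
    start_times: list[float] = field(default_factory=list)  # per-task compute start
    finish_time: float = 0.0
    stalls: int = 0          # compute waits for input after the first chunk
    n_tasks: int = 0


class ThreadPool:
    """Worker groups as threads, each fed by its own prefetching loader.

    The loader role stages chunks into a bounded two-slot queue (double
    buffer) so that, with in-memory inputs, a worker never waits for data
    after its first chunk. All instrumentation is wall-clock.
    """

    def __init__(self, n_workers: int):
        if n_workers < 1:
            raise ValueError("pool must have at least 1 worker")
        self.n_workers = n_workers

    def run(
        self, assignments: Sequence[Sequence[Chunk]], work_fn: Callable[[Chunk], object]
    ) -> tuple[dict[int, object], list[WorkerStats], float]:
        """Execute per-worker chunk lists; returns (results, stats, wall span)."""
        results: dict[int, object] = {}
        lock = threading.Lock()
        stats = [WorkerStats(w) for w in range(self.n_workers)]
        errors: list[BaseException] = []
        epoch = time.perf_counter()

        def loader(w: int, buf: "queue.Queue") -> None:
            for chunk in assignments[w]:
                buf.put(chunk)
            buf.put(None)

        def worker(w: int, buf: "queue.Queue") -> None:
            st = stats[w]
            first = True
            try:
                while True:
                    if not first and buf.empty():
                        st.stalls += 1
                    chunk = buf.get()
                    if chunk is None:
                        break
                    t0 = time.perf_counter() - epoch
                    res = work_fn(chunk)
                    t1 = time.perf_counter() - epoch
                    st.start_times.append(t0)
                    st.busy_time += t1 - t0
                    st.finish_time = t1
                    st.n_tasks += 1
                    first = False
                    with lock:
                        results[chunk.chunk_id] = res
            except BaseException as exc:  # surfaced to the caller below
                errors.append(exc)

        threads = []
        for w in range(self.n_workers):
            buf: "queue.Queue" = queue.Queue(maxsize=2)
            tl = threading.Thread(target=loader, args=(w, buf), daemon=True)
            tw = threading.Thread(target=worker, args=(w, buf), daemon=True)
            tl.start()
            tw.start()
            threads.extend([tl, tw])
        for t in threads:
            t.join()
        if errors:
            raise errors[0]
        span = max((st.finish_time for st in stats if st.n_tasks), default=0.0)
        return results, stats, span


class SimulatedPool:
    """Deterministic discrete-event pool with heterogeneous worker speeds.

    Each worker processes one peak in ``1 / speed`` time units; loading a
    chunk of L peaks costs ``load_time_per_item * L``. With ``prefetch``
    on, the loader stages the next chunk into a second buffer while the
    current one computes, and a stall is recorded whenever compute must
    wait for a load to finish after the first chunk. ``work_fn`` (when
    given) is evaluated eagerly and serially, so results are exact and
    reproducible while time remains simulated.
    """

    def __init__(
        self,
        speeds: Sequence[float],
        load_time_per_item: float = 0.0,
        prefetch: bool = True,
    ):
        if len(speeds) < 1:
            raise ValueError("pool must have at least 1 worker")
        if any(s <= 0 for s in speeds):
            raise ValueError("worker speeds must be positive")
        self.speeds = [float(s) for s in speeds]
        self.n_workers = len(speeds)
        self.load_time_per_item = load_time_per_item
        self.prefetch = prefetch

    def compute_time(self, chunk: Chunk, worker_id: int) -> float:
        return chunk.total_length / self.speeds[worker_id]

    def load_time(self, chunk: Chunk) -> float:
        return self.load_time_per_item * chunk.total_length

    def run(
        self,
        assignments: Sequence[Sequence[Chunk]],
        work_fn: Callable[[Chunk], object] | None = None,
    ) -> tuple[dict[int, object], list[WorkerStats], float]:
        results: dict[int, object] = {}
        stats = [WorkerStats(w) for w in range(self.n_workers)]
        for w in range(self.n_workers):
            st = stats[w]
            chunks = list(assignments[w])
            load_end = [0.0] * len(chunks)
            comp_end_prev2 = 0.0  # compute end of chunk k-2 (its buffer frees then)
            comp_end_prev = 0.0
            t_load_cursor = 0.0
            for k, chunk in enumerate(chunks):
                if self.prefetch:
                    # loader may run ahead by one buffer slot
                    start_load = max(t_load_cursor, comp_end_prev2)
                else:
                    start_load = comp_end_prev
                load_end[k] = start_load + self.load_time(chunk)
                t_load_cursor = load_end[k]
                start_comp = max(comp_end_prev, load_end[k])
                if k > 0 and load_end[k] > comp_end_prev:
                    st.stalls += 1
                dur = self.compute_time(chunk, w)
                st.start_times.append(start_comp)
                st.busy_time += dur
                comp_end_prev2 = comp_end_prev
                comp_end_prev = start_comp + dur
                st.n_tasks += 1
                if work_fn is not None:
                    results[chunk.chunk_id] = work_fn(chunk)
            st.finish_time = comp_end_prev
        span = max((st.finish_time for st in stats if st.n_tasks), default=0.0)
        return results, stats, span


# ---------------------------------------------------------------------------
# probe, feedback factor, allocation


def probe(
    sample_chunks: Sequence[Chunk],
    pool,
    work_fn: Callable[[Chunk], object] | None = None,
    w_util: float = 0.5,
    w_queue: float = 0.5,
) -> tuple[list[WorkerFeedback], dict[int, object]]:
    """Run a small chunk sample to measure worker availability.

    Chunks are dealt round-robin (chunk *i* to worker ``i % n``). For each
    worker, utilization is its busy time over the common probe wall span,
    and the mean queue length is the time-average of tasks still waiting
    in its queue (the running task excluded). Returns the feedback records
    with normalized regulatory factors, plus any results computed during
    the probe so they need not be recomputed.
    """
    n = getattr(pool, "n_workers", 0)
    if n < 1:
        raise ValueError("pool must have at least 1 worker")
    if len(sample_chunks) < n:
        raise ValueError(f"need >= 1 probe chunk per worker ({n}), got {len(sample_chunks)}")
    assignments: list[list[Chunk]] = [list(sample_chunks[w::n]) for w in range(n)]
    results, stats, span = pool.run(assignments, work_fn)
    return feedback_from_stats(stats, span, w_util, w_queue), results


def feedback_from_stats(
    stats: Sequence[WorkerStats], span: float, w_util: float = 0.5, w_queue: float = 0.5
) -> list[WorkerFeedback]:
    """Convert execution timings into normalized worker feedback.

    Utilization is busy time over the common wall span; the mean queue
    length is the time-average of tasks still waiting in the worker's
    queue (each task waits from t = 0 until its compute starts, so the
    waiting integral is the sum of compute start times).
    """
    feedbacks = []
    for st in stats:
        if span > 0:
            util = min(1.0, st.busy_time / span)
            waiting_integral = sum(st.start_times)
            qlen = waiting_integral / span
        else:
            util, qlen = 0.0, 0.0
        feedbacks.append(WorkerFeedback(st.worker_id, util, qlen))
    raw = [regulatory_factor(fb, w_util, w_queue) for fb in feedbacks]
    total = sum(raw)
    n = len(feedbacks)
    for fb, r in zip(feedbacks, raw):
        fb.regulatory_factor = r / total if total > 0 else 1.0 / n
    return feedbacks


def sample_probe_chunks(chunks: Sequence[Chunk], n_workers: int, seed: int) -> list[Chunk]:
    """Seeded random contiguous window of ``n_workers`` probe chunks.

    Adjacent chunks hold near-equal peak counts (the groups behind them are
    length-sorted), so a contiguous window hands every worker a probe task
    of comparable cost: the measured utilization then reflects worker
    availability rather than task-size luck.
    """
    if len(chunks) < n_workers:
        raise ValueError("need at least one chunk per worker to probe")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(chunks) - n_workers + 1))
    return list(chunks[start : start + n_workers])


def regulatory_factor(fb: WorkerFeedback, w_util: float = 0.5, w_queue: float = 0.5) -> float:
    """Raw feedback regulatory factor of one worker (before normalization).

    A linear blend of spare capacity and queue headroom:
    ``w_util * (1 - utilization) + w_queue / (1 + mean_queue_length)``.
    An idle worker with an empty queue scores 1; a saturated worker with a
    long backlog tends to 0 and is starved of new chunks.
    """
    if w_util < 0 or w_queue < 0 or abs(w_util + w_queue - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return w_util * (1.0 - fb.utilization) + w_queue / (1.0 + fb.mean_queue_length)


def allocate(chunks: Sequence[Chunk], factors: Sequence[float]) -> Allocation:
    """Apportion chunks to workers proportionally to their feedback factors.

    Chunk *counts* follow largest-remainder apportionment on the factors
    (so each count differs from exact proportionality by less than one);
    chunk *positions* are dealt in id order to the worker with the lowest
    filled fraction, which spreads every worker's share evenly across the
    length-sorted sequence. Within a worker, chunks stay in id order.
    """
    n = len(factors)
    if n < 1:
        raise ValueError("need at least one worker factor")
    total = len(chunks)
    quotas = np.asarray(factors, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainders = quotas - np.floor(quotas)
        for w in sorted(range(n), key=lambda i: (-remainders[i], i))[:short]:
            counts[w] += 1
    assignment: dict[int, int] = {}
    per_worker: list[list[int]] = [[] for _ in range(n)]
    assigned = [0] * n
    for chunk in sorted(chunks, key=lambda c: c.chunk_id):
        best_w, best_key = -1, None
        for w in range(n):
            if assigned[w] >= counts[w]:
                continue
            key = ((assigned[w] + 1) / counts[w], w)
            if best_key is None or key < best_key:
                best_w, best_key = w, key
        assignment[chunk.chunk_id] = best_w
        per_worker[best_w].append(chunk.chunk_id)
        assigned[best_w] += 1
    by_id = {c.chunk_id: c for c in chunks}
    loads = [float(sum(by_id[cid].total_length for cid in per_worker[w])) for w in range(n)]
    return Allocation(assignment, loads, per_worker)


# ---------------------------------------------------------------------------
# pipeline drivers


def process_spectrum(s: Spectrum, config: RunConfig) -> PSM:
    """The per-spectrum sequencing pipeline: filter → graph → enumerate → score."""
    table = config.residue_table()
    filtered = effective_peaks(s, config.window, config.keep_per_window)
    g = build_graph(filtered, table, config.fragment_tol, config.effective_merge_tol)
    tags = None
    if config.tag_filter:
        tags = set(extract_tags(g, config.tag_length))
    cands = enumerate_candidates(
        g,
        table,
        precursor_tol=config.precursor_tol,
        max_length=config.max_length,
        cap=config.max_candidates,
        tags=tags,
        tag_length=config.tag_length,
    )
    return score_candidates(
        filtered, cands, table, config.effective_bin_width, config.sqrt_intensity
    )


def _safe_process(s: Spectrum, config: RunConfig) -> PSM:
    try:
        return process_spectrum(s, config)
    except Exception:
        log.warning("spectrum %s failed; emitting empty PSM", s.id, exc_info=True)
        return PSM(s.id, None, 0.0, s.parent_mass)


def run_serial(spectra: Sequence[Spectrum], config: RunConfig) -> list[PSM]:
    """Reference single-worker pipeline; output in input-spectrum order."""
    return [_safe_process(s, config) for s in spectra]


def run_parallel(
    spectra: Sequence[Spectrum],
    config: RunConfig,
    pool=None,
    report: dict | None = None,
) -> list[PSM]:
    """Batch-parallel pipeline; output identical to :func:`run_serial`.

    Spectra are sorted, concatenated into groups, chunked, and assigned to
    workers by the probe/feedback/allocate scheme; each worker's loader
    prefetches chunks while it computes. Results are reassembled into the
    original input order, so for every spectrum the returned PSM (peptide
    and bit-identical score) equals the serial one. Pass a ``report`` dict
    to receive scheduling diagnostics (chunk count, allocation imbalance,
    stall count).
    """
    if pool is None:
        pool = ThreadPool(config.workers)
    if not spectra:
        return []

    ordered = sort_spectra(spectra)
    groups = concatenate_groups(ordered)
    chunks = make_chunks(groups, pool.n_workers, config.groups_per_chunk)

    def work(chunk: Chunk) -> list[PSM]:
        return [_safe_process(s, config) for s in chunk.spectra()]

    if len(chunks) < pool.n_workers:  # degenerate tiny datasets: skip the probe
        feedbacks = [
            WorkerFeedback(w, 0.0, 0.0, 1.0 / pool.n_workers) for w in range(pool.n_workers)
        ]
        results: dict[int, object] = {}
    else:
        probe_chunks = sample_probe_chunks(chunks, pool.n_workers, config.seed)
        feedbacks, results = probe(probe_chunks, pool, work)

    # allocation waves: with re-probing enabled, feedback measured while
    # executing one wave steers the allocation of the next
    wave_size = config.reprobe_every if config.reprobe_every > 0 else len(chunks)
    total_loads = np.zeros(pool.n_workers)
    total_stalls = 0
    total_span = 0.0
    for start in range(0, len(chunks), max(1, wave_size)):
        wave = chunks[start : start + wave_size]
        alloc = allocate(wave, [fb.regulatory_factor for fb in feedbacks])
        remaining = [
            [chunks[cid] for cid in per_w if cid not in results] for per_w in alloc.per_worker
        ]
        wave_results, stats, span = pool.run(remaining, work)
        results.update(wave_results)
        total_loads += np.asarray(alloc.loads)
        total_stalls += sum(st.stalls for st in stats)
        total_span += span
        if config.reprobe_every > 0 and any(st.n_tasks for st in stats):
            feedbacks = feedback_from_stats(stats, span)

    if report is not None:
        report.update(
            n_chunks=len(chunks),
            n_groups=len(groups),
            imbalance_percent=load_imbalance_percent(total_loads),
            stalls=total_stalls,
            factors=[fb.regulatory_factor for fb in feedbacks],
            wall_span=total_span,
        )

    # reassemble: chunk results are in sorted order; map back by object identity
    positions: dict[int, list[int]] = {}
    for i, s in enumerate(spectra):
        positions.setdefault(id(s), []).append(i)
    out: list[PSM | None] = [None] * len(spectra)
    for chunk in chunks:
        chunk_psms = results[chunk.chunk_id]
        for s, psm in zip(chunk.spectra(), chunk_psms):
            out[positions[id(s)].pop(0)] = psm
    assert all(p is not None for p in out)
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# scheduler benchmark


def bench_scheduler(
    n_spectra: int = 1000,
    speeds: Sequence[float] = (1.0, 0.8, 1.2, 0.9),
    seed: int = 0,
    replicates: int = 20,
    groups_per_chunk: int = 2,
) -> dict:
    """Measure achieved load imbalance of the feedback scheduler.

    For each replicate, ``n_spectra`` synthetic spectra are generated,
    transformed (sort → concatenate → chunk) and allocated to a
    discrete-event pool of heterogeneous workers after a one-chunk-per-
    worker probe. The reported load of a worker is its assigned peak count
    divided by its speed (i.e. its simulated busy time), and the imbalance
    is (max − mean)/mean × 100 over workers. Returns per-replicate
    imbalances and their median.
    """
    from .synthetic_data import DatasetParams, generate_spectra

    rng = np.random.default_rng(seed)
    imbalances = []
    for _ in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spectra, _truth = generate_spectra(n_spectra, DatasetParams(), seed=rep_seed)
        pool = SimulatedPool(speeds)
        ordered = sort_spectra(spectra)
        groups = concatenate_groups(ordered)
        chunks = make_chunks(groups, pool.n_workers, groups_per_chunk)
        feedbacks, _ = probe(sample_probe_chunks(chunks, pool.n_workers, rep_seed + 1), pool)
        alloc = allocate(chunks, [fb.regulatory_factor for fb in feedbacks])
        weighted = [alloc.loads[w] / pool.speeds[w] for w in range(pool.n_workers)]
        imbalances.append(load_imbalance_percent(weighted))
    return {
        "imbalances": imbalances,
        "median": float(np.median(imbalances)),
        "speeds": list(speeds),
        "n_spectra": n_spectra,
        "replicates": replicates,
    }
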