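"""Data transformation, feedback scheduling, pools and pipeline drivers."""

import numpy as np
import pytest

from denovopep.batch_sched import (
    Chunk,
    SimulatedPool,
    SpectrumGroup,
    ThreadPool,
    WorkerFeedback,
    allocate,
    concatenate_groups,
    load_imbalance_percent,
    make_chunks,
    probe,
    regulatory_factor,
    run_parallel,
    run_serial,
    sort_spectra,
)
from denovopep.config import RunConfig
from denovopep.spectra_io import Spectrum
from denovopep.synthetic_data import DatasetParams, NoiseParams, generate_spectra


def _spec(n_peaks, sid="s", start=100.0):
    mz = start + np.arange(n_peaks, dtype=float)
    return Spectrum(sid, 500.0, 2, 900.0, mz, np.ones(n_peaks))


def _groups(lengths):
    return [SpectrumGroup([_spec(n, f"g{i}")]) for i, n in enumerate(lengths)]


class TestSort:
    def test_ascending_by_length(self):
        out = sort_spectra([_spec(12, "a"), _spec(3, "b"), _spec(7, "c")])
        assert [s.length for s in out] == [3, 7, 12]

    def test_ties_broken_by_id(self):
        out = sort_spectra([_spec(5, "z"), _spec(5, "a"), _spec(5, "m")])
        assert [s.id for s in out] == ["a", "m", "z"]

    def test_empty(self):
        assert sort_spectra([]) == []


class TestConcatenate:
    def test_greedy_packing_trace(self):
        spectra = [_spec(n, f"s{n}") for n in (3, 4, 5, 10)]
        groups = concatenate_groups(spectra)
        assert [g.total_length for g in groups] == [7, 5, 10]

    def test_single_spectrum_singleton(self):
        groups = concatenate_groups([_spec(6)])
        assert len(groups) == 1 and groups[0].total_length == 6

    def test_partition_and_bound(self):
        rng = np.random.default_rng(3)
        spectra = [_spec(int(n), f"s{i}") for i, n in enumerate(rng.integers(1, 60, size=200))]
        ordered = sort_spectra(spectra)
        groups = concatenate_groups(ordered)
        target = max(s.length for s in spectra)
        flat = [s for g in groups for s in g.members]
        assert flat == ordered  # groups partition the sorted list, order kept
        assert all(g.total_length <= target for g in groups)

    def test_serialization_inserts_terminators(self):
        g = SpectrumGroup([_spec(2, "a"), _spec(3, "b")])
        layout = g.serialize()
        assert len(layout) == 3 and layout[0].id == "a" and layout[2].id == "b"


class TestMakeChunks:
    def test_exact_multiple(self):
        chunks = make_chunks(_groups([5] * 8), n_workers=4, groups_per_chunk=2)
        assert len(chunks) == 4
        assert all(len(c.groups) == 2 for c in chunks)
        assert [c.chunk_id for c in chunks] == [0, 1, 2, 3]

    def test_single_group(self):
        chunks = make_chunks(_groups([5]), n_workers=4, groups_per_chunk=2)
        assert len(chunks) == 1

    def test_reshaping_toward_worker_multiple(self):
        chunks = make_chunks(_groups([5] * 10), n_workers=4, groups_per_chunk=2)
        assert len(chunks) % 4 == 0  # 5 naive chunks reshaped to 8
        ids = [g.members[0].id for c in chunks for g in c.groups]
        assert ids == [f"g{i}" for i in range(10)]  # group order preserved

    def test_unsplittable_keeps_count(self):
        chunks = make_chunks(_groups([5] * 3), n_workers=4, groups_per_chunk=1)
        assert len(chunks) == 3  # all singletons, nothing to split


class TestFeedbackFactor:
    def test_plug_in_value(self):
        fb = WorkerFeedback(0, utilization=0.5, mean_queue_length=1.0)
        assert regulatory_factor(fb, 0.5, 0.5) == pytest.approx(0.5)

    def test_saturated_worker_tends_to_zero(self):
        fb = WorkerFeedback(0, utilization=1.0, mean_queue_length=1e9)
        assert regulatory_factor(fb, 0.5, 0.5) == pytest.approx(0.0, abs=1e-8)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            regulatory_factor(WorkerFeedback(0, 0.5, 0.5), 0.7, 0.5)

    def test_identical_workers_get_equal_shares(self):
        chunks = make_chunks(_groups([5] * 4), n_workers=2, groups_per_chunk=1)
        feedbacks, _ = probe(chunks[:2], SimulatedPool([1.0, 1.0]))
        assert feedbacks[0].regulatory_factor == pytest.approx(0.5)
        assert feedbacks[1].regulatory_factor == pytest.approx(0.5)


class TestProbe:
    def test_single_worker_bounds(self):
        chunks = make_chunks(_groups([5, 5]), n_workers=1, groups_per_chunk=1)
        feedbacks, _ = probe(chunks, SimulatedPool([1.0]))
        (fb,) = feedbacks
        assert 0.0 <= fb.utilization <= 1.0
        assert fb.mean_queue_length >= 0.0
        assert fb.regulatory_factor == 1.0

    def test_slower_worker_has_lower_availability(self):
        # discrete-event oracle: at half speed, busy time doubles, so the
        # slow worker saturates the probe span and earns a smaller factor
        chunks = make_chunks(_groups([10] * 4), n_workers=2, groups_per_chunk=1)
        feedbacks, _ = probe(chunks[:2], SimulatedPool([1.0, 0.5]))
        assert feedbacks[1].utilization > feedbacks[0].utilization
        assert feedbacks[1].regulatory_factor < feedbacks[0].regulatory_factor

    def test_requires_chunk_per_worker(self):
        chunks = make_chunks(_groups([5]), n_workers=1, groups_per_chunk=1)
        with pytest.raises(ValueError):
            probe(chunks, SimulatedPool([1.0, 1.0]))

    def test_zero_worker_pool_rejected(self):
        with pytest.raises(ValueError):
            SimulatedPool([])


class TestAllocate:
    def test_exact_proportions(self):
        chunks = make_chunks(_groups([5] * 8), n_workers=1, groups_per_chunk=1)
        alloc = allocate(chunks, [0.5, 0.25, 0.25])
        counts = [len(w) for w in alloc.per_worker]
        assert counts == [4, 2, 2]
        assert sorted(alloc.assignment) == list(range(8))

    def test_imbalance_formula(self):
        assert load_imbalance_percent([110.0, 90.0]) == pytest.approx(10.0)

    def test_equal_factors_equal_chunks_no_imbalance(self):
        chunks = make_chunks(_groups([5] * 8), n_workers=4, groups_per_chunk=1)
        alloc = allocate(chunks, [0.25] * 4)
        assert alloc.imbalance_percent == pytest.approx(0.0)

    def test_counts_within_one_of_proportionality(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n_chunks = int(rng.integers(1, 40))
            chunks = make_chunks(_groups([3] * n_chunks), n_workers=1, groups_per_chunk=1)
            raw = rng.random(4) + 0.05
            factors = raw / raw.sum()
            alloc = allocate(chunks, factors)
            for w, ids in enumerate(alloc.per_worker):
                assert abs(len(ids) - factors[w] * n_chunks) < 1.0


class TestSimulatedPoolPrefetch:
    def _assign(self, n_chunks, lengths=10):
        chunks = make_chunks(_groups([lengths] * n_chunks), n_workers=1, groups_per_chunk=1)
        return [chunks]

    def test_no_stalls_when_load_faster_than_compute(self):
        pool = SimulatedPool([1.0], load_time_per_item=0.2, prefetch=True)
        _, stats, _ = pool.run(self._assign(10), None)
        assert stats[0].stalls == 0

    def test_stalls_without_prefetch_counted_as_serial_time(self):
        fast_load = SimulatedPool([1.0], load_time_per_item=0.2, prefetch=True)
        no_prefetch = SimulatedPool([1.0], load_time_per_item=0.2, prefetch=False)
        _, _, span_pf = fast_load.run(self._assign(10), None)
        _, _, span_np = no_prefetch.run(self._assign(10), None)
        assert span_pf < span_np  # overlap hides load time

    def test_slow_loader_stalls_compute(self):
        pool = SimulatedPool([1.0], load_time_per_item=2.0, prefetch=True)
        _, stats, _ = pool.run(self._assign(10), None)
        assert stats[0].stalls == 9  # every chunk after the first waits


class TestPipeline:
    def test_clean_spectrum_recovered_end_to_end(self, table):
        from denovopep.scoring import theoretical_spectrum

        theo = theoretical_spectrum("GAVLK", table)
        cfg = RunConfig(fixed_mods=(), variable_mods=())
        (psm,) = run_serial([theo], cfg)
        assert psm.sequence_str == "GAVLK"
        assert psm.score == 1.0

    def test_empty_input(self):
        assert run_serial([], RunConfig()) == []
        assert run_parallel([], RunConfig()) == []

    def test_no_path_yields_empty_psm(self):
        s = Spectrum("dead", 31.01256, 2, 60.0)  # sink below any residue mass
        (psm,) = run_serial([s], RunConfig())
        assert psm.sequence_str == "" and psm.score == 0.0

    @pytest.mark.parametrize("workers", [1, 2, 4])
    def test_parallel_identical_to_serial(self, workers):
        spectra, _ = generate_spectra(40, DatasetParams(), seed=13)
        cfg = RunConfig(workers=workers, seed=5)
        ser = run_serial(spectra, cfg)
        par = run_parallel(spectra, cfg)
        for a, b in zip(ser, par):
            assert a.spectrum_id == b.spectrum_id
            assert a.sequence_str == b.sequence_str
            assert a.score == b.score  # bit-identical

    def test_parallel_identical_on_simulated_heterogeneous_pool(self):
        spectra, _ = generate_spectra(30, DatasetParams(), seed=17)
        cfg = RunConfig(workers=4, seed=5)
        ser = run_serial(spectra, cfg)
        pool = SimulatedPool([1.0, 0.8, 1.2, 0.9], load_time_per_item=0.05)
        par = run_parallel(spectra, cfg, pool=pool)
        assert [(p.sequence_str, p.score) for p in par] == [
            (p.sequence_str, p.score) for p in ser
        ]

    def test_reprobe_waves_preserve_identity(self):
        spectra, _ = generate_spectra(30, DatasetParams(), seed=19)
        ser = run_serial(spectra, RunConfig())
        cfg = RunConfig(workers=2, seed=5, reprobe_every=3)
        par = run_parallel(spectra, cfg)
        assert [(p.sequence_str, p.score) for p in par] == [
            (p.sequence_str, p.score) for p in ser
        ]

    def test_report_diagnostics(self):
        spectra, _ = generate_spectra(30, DatasetParams(), seed=23)
        report = {}
        run_parallel(spectra, RunConfig(workers=2, seed=5), report=report)
        assert report["n_chunks"] >= 1
        assert report["imbalance_percent"] >= 0.0
        assert abs(sum(report["factors"]) - 1.0) < 1e-9
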