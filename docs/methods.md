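# Methods

This note documents the models, numerical choices and limitations behind
`denovopep`: the spectrum-graph sequencing engine, the cosine match
score, the batch-parallel scheduling framework, and the synthetic-data
generator the tests rely on.

## Chemistry and constants

All masses are monoisotopic daltons. The proton is 1.00728 Da and water
18.01056 Da (`denovopep.constants`, the single source of truth). The
residue table holds the 20 standard amino acids; fixed modifications
shift a residue mass in place (default: carbamidomethyl-cysteine,
C+57.02146) and each variable modification adds a starred symbol
alongside the unmodified one (default: oxidized methionine,
M* = M+15.99491). Nominal deltas in config strings (`C+57`, `M+16`)
resolve to their monoisotopic values.

Two residue pairs are effectively indistinguishable at the default
0.75 Da fragment tolerance: I/L (exactly isobaric) and K/Q (Δ =
0.03638 Da). Edges collapse exact isobars onto one canonical label (L);
`unambiguous_alphabet(tol)` returns the alphabet with one canonical
member per mass-indistinguishable group, which the clean-recovery tests
use so that "exact sequence recovery" is well defined.

## Spectrum graph

Nodes live on the prefix-residue-mass (PRM) axis rather than raw m/z:
each peak yields a b interpretation (mz − proton) and a y interpretation
(M + proton − mz), values outside the open interval (0, sink) are
discarded, and the source 0 and sink M − water are always present. This
is the standard coordinate in which "two nodes differ by one residue
mass" is meaningful for both ion series at once.

Numerical choices:

- **Node clustering.** Interpretations are single-linkage clustered at a
  merge tolerance (default: fragment_tol / 2) and each cluster is
  replaced by its support-weighted mean, so coincident b/y evidence for
  the same prefix fuses into one node. Clusters touching the source or
  sink snap to those exact anchors; the graph ends can neither drift nor
  be merged away.
- **Reachability pruning.** After edge construction, nodes on no
  source→sink path are removed. A candidate is by definition a full
  source→sink path, so pruning provably cannot change the enumeration
  output; it removes mirror-image interpretation artifacts (the
  y-reading of a b peak and vice versa) and shrinks the search. Tags are
  read from the pruned graph for the same reason.
- **Edges.** u→v is labelled r when |(v − u) − m(r)| ≤ fragment_tol;
  only singly-charged b/y interpretations are made (the dominant CID
  series). a/c/x/z ions, multiply-charged fragments and neutral losses
  are out of scope.

## Candidate enumeration

Depth-first search from the source, deterministic edge order (ascending
target mass, then label), emitting a candidate whenever the sink node is
reached within `max_length` edges (default 30) with a residue-mass sum
within the precursor tolerance of the sink. Branches die when the
remaining mass cannot be bridged by the hops left (too far for all-W
steps, or less than one G above tolerance). Enumeration stops collecting
at the cap (default 10,000); because the DFS order is fixed, the
collected set is deterministic, and it is then ordered by descending
summed node support with lexicographic tie-break. Applying the cap
during collection rather than after a complete enumeration is what makes
it an effective cost bound on dense noisy graphs.

An exhaustive oracle (`brute_force_candidates`, refused above length 6)
enumerates every sequence over the table whose mass hits the target;
the equivalence tests check DFS output against it on random instances
whose node sets are exact prefix sums.

Tag extraction (all length-k path strings, default k = 6) is available
as an optional candidate pre-filter and is off by default, since the
enumeration is already mass-constrained.

## Match scoring

The only similarity adopted is the binned cosine: both the experimental
spectrum and the candidate's unit-intensity theoretical b/y ladder are
accumulated into floor(mz / bin_width) bins (bin width = fragment
tolerance, binning up to parent_mass + 50 Da) and compared by cosine,
which is bounded in [0, 1] for non-negative intensities. Experimental
intensities are square-root transformed by default to damp dominant
peaks; cosine's scale invariance makes further normalisation
unnecessary.

Two deliberate numerical guards: bit-identical vectors score exactly
1.0 (the mathematically exact value, bypassing dot-product rounding) and
results are clamped into [0, 1]. Without the first guard, rounding noise
of order 1e-16 can defeat the deterministic tie-break (best score, then
lexicographically smallest sequence) that the serial/parallel identity
contract relies on. The best candidate is selected by a full scan with
that tie-break, so the result is independent of candidate order.

## Batch scheduling

The two-level hierarchy (manager distributing chunks to worker groups;
a loader role inside each worker prefetching the next chunk) is emulated
portably: the contract is ordering and identity of results, never a
hardware primitive.

- **Data transformation.** Spectra are sorted ascending by peak count
  (ties by id, stable), then greedily concatenated left-to-right into
  groups whose total never exceeds the longest single spectrum; groups
  are packed `groups_per_chunk` (default 2) at a time into chunks, and
  trailing multi-group chunks are split one group at a time until the
  chunk count is a multiple of the worker count when possible.
- **Probe.** One chunk per worker, taken as a seeded random *contiguous
  window* of the chunk sequence. Adjacent chunks are near-equal in size
  (their groups are length-sorted), so a contiguous window gives every
  worker a probe task of comparable cost and the measured utilization
  reflects worker availability rather than task-size luck; scattered
  sampling was measurably noisier for exactly this reason. Utilization
  is busy time over the common probe wall span; mean queue length is the
  time-average of tasks still *waiting* in the worker's queue (the
  running task excluded) — with each task queued at t = 0, the waiting
  integral is the sum of compute start times.
- **Feedback factor and allocation.** The raw factor is the linear blend
  0.5·(1 − U) + 0.5/(1 + Q), normalized to sum to 1 across workers.
  Chunk counts follow largest-remainder apportionment (each worker's
  count is within 1 of exact proportionality) and positions are dealt in
  id order to the worker with the lowest filled fraction, spreading each
  worker's share evenly across the length-sorted sequence. Load
  imbalance is reported as (max − mean)/mean × 100 over per-worker
  loads. Optional re-probing (`reprobe_every`) allocates chunks in
  waves, steering each wave by feedback measured during the previous
  one; it is off by default.
- **Pools.** `ThreadPool` runs chunks on real threads, each fed by its
  own loader thread through a two-slot queue (double buffer), with
  wall-clock instrumentation. `SimulatedPool` is a deterministic
  discrete-event model: a worker with speed s processes a peak in 1/s
  time units, loads may overlap the previous chunk's compute when
  prefetch is on, and a stall is counted whenever compute waits for a
  load after the first chunk (zero stalls whenever per-chunk load time
  is below compute time). The scheduler benchmark and its acceptance
  measurement run on the simulated pool, so they are exactly
  reproducible from the seed.
- **Identity.** `run_parallel` reassembles chunk results into original
  input order by object identity, and every PSM is produced by the same
  pure per-spectrum pipeline regardless of worker; serial and parallel
  outputs are therefore bit-identical, which the tests assert for worker
  counts 1/2/4 across seeds, on both pools, with and without re-probing.

## Synthetic data

The generator emulates tryptic peptides (uniform residues, terminal K/R,
length uniform in 7–13 by default so the mean is 10) fragmented into
singly-charged b/y ladders observed at precursor charge 2. Peptides are
simulated with the fixed modification applied (carbamidomethyl-C by
default) so the generated chemistry matches the default interpretation
table — without this, cysteine-containing peptides would be
systematically unreadable because modified C weighs exactly C + G.

Noise model (all defaults chosen once): each true peak gets a log-normal
intensity with unit median and CV 0.3; peaks drop out independently with
probability 0.1; surviving peaks are jittered with Gaussian m/z error of
SD 0.1 Da (|jitter| < 0.75 Da is a 7.5σ event, so true peaks stay within
the fragment tolerance); 20 contaminant peaks are uniform in (50,
parent + 50) Da with median intensity 0.3 of the signal's.

What it does *not* emulate: isotope envelopes, multiply-charged or
neutral-loss fragments, correlated intensity structure along the ladder,
retention time, or instrument-specific noise. Passing tests on this
generator therefore demonstrate the pipeline's correctness and its
behaviour under idealised noise, not identification rates on real
instrument data; on real spectra the simple cosine score would rank far
below trained scorers.

## Problem sizes used by the test suite

The suite's end-to-end checks use the sizes their properties need rather
than production volumes: identity on 500 spectra × worker counts 1/2/4 ×
3 seeds; clean recovery on 200 spectra (observed 199/200 with the
ambiguity-free alphabet, where the single failure is a mass-ambiguous
reading); oracle equivalence on 100 random instances; scheduler
benchmark on 1,000 spectra × 20 replicates (observed median imbalance
≈ 4.6% for speeds 1.0/0.8/1.2/0.9, against the ≤ 9% design goal).

## Known limitations

- Incomplete ladders break paths: a spectrum missing both the b and y
  witness of an internal prefix has no source→sink path and yields an
  empty PSM (no gapped edges spanning two residues are attempted).
- Exact-sequence recovery is bounded by mass ambiguity (I/L always, K/Q
  and compound substitutions like GG↔N at loose tolerances); such ties
  resolve deterministically (lexicographic) but not necessarily to the
  generating sequence.
- The thread-based pool offers concurrency, not CPython speedup, for
  this pure-Python workload; the framework's value here is the
  scheduling behaviour and the identity guarantee.
- Only singly-charged precursor-derived b/y interpretation is performed;
  charge states other than the header value are not deconvolved.
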