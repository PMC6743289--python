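# denovopep

De novo peptide sequencing of tandem mass spectra (MS/MS), built as a
spectrum-graph peptide-spectrum-match (PSM) engine wrapped in a
batch-parallel scheduling framework whose parallel output is guaranteed
identical to its serial reference.

It is aimed at people who want a small, fully inspectable de novo
sequencer: proteomics students, method developers who need a transparent
baseline, and anyone studying how to schedule large MS/MS batches over
heterogeneous workers.

## What it computes

Given an MS/MS spectrum with precursor m/z and charge, the neutral
peptide mass is M = mz·z − z·m(H⁺). Each fragment peak is interpreted as
a singly-charged b ion (prefix + H⁺) and as a y ion (suffix + H₂O + H⁺),
and both interpretations are mapped to the common *prefix residue mass*
(PRM) axis. The clustered interpretations become the nodes of a
**spectrum graph** — a DAG that always contains the source 0 and the
sink M − m(H₂O) — with an edge u→v labelled by residue r whenever
|(v − u) − m(r)| ≤ τ_f (fragment tolerance, default 0.75 Da). A
**candidate peptide** is a source→sink path whose residue masses sum to
the sink within the precursor tolerance τ_p (default 2 Da). Candidates
are scored against the experimental spectrum by cosine similarity of
binned intensity vectors (bin width = τ_f),

    score(P, S) = ⟨b(S), b(T(P))⟩ / (‖b(S)‖ · ‖b(T(P))‖) ∈ [0, 1],

where T(P) is the unit-intensity theoretical b/y ladder of P; the top-1
candidate is the reported PSM. Fixed carbamidomethyl-cysteine (C+57.02146)
and variable methionine oxidation (M* = M+15.99491) are on by default.

For large batches, spectra are sorted by peak count, concatenated into
groups bounded by the longest spectrum, and packed into chunks. A short
seeded probe measures each worker group's utilization U and mean queue
length Q, from which a **feedback regulatory factor**

    f ∝ 0.5·(1 − U) + 0.5/(1 + Q)

apportions chunk counts across workers (largest-remainder). Inside each
worker a loader role prefetches the next chunk while the current one
computes (double buffering). Scheduling only decides *who* computes
*what*: `run_parallel` returns bit-identical PSMs to `run_serial`.

## Worked example

Simulate 200 tryptic spectra with realistic noise (10% peak dropout, 20
contaminant peaks, 0.1 Da m/z jitter), then sequence them on 4 workers:

```sh
$ denovopep simulate -n 200 --seed 11 -o demo
demo/synthetic.mgf
demo/synthetic_truth.tsv
$ denovopep run --input demo/synthetic.mgf --output demo/psms.tsv --workers 4 --seed 11
... INFO denovopep: read 200 spectra in 0.01s
... INFO denovopep: parallel pipeline: 3.17s (100 chunks on 4 workers, allocation imbalance 19.77%, 0 stalls)
... INFO denovopep: wrote 200 PSMs to demo/psms.tsv
$ head -3 demo/psms.tsv
spectrum_id	peptide	score	parent_mass
synthetic_0000	DSLNPRK	0.664756906115204	828.44535
synthetic_0001	YRVADCMR	0.6656189925291661	1069.4797099999998
```

Each row is the top-1 PSM: the inferred sequence, its cosine score in
[0, 1], and the neutral parent mass in Da. Running the same command with
`--serial` produces a byte-identical TSV — that is the core contract.

On noise-free spectra the engine is near-exact once mass-indistinguishable
residues are excluded (I/L are isobaric; K/Q differ by 0.036 Da, far below
a 0.75 Da tolerance):

```python
from denovopep import RunConfig, run_serial
from denovopep.synthetic_data import (DatasetParams, NoiseParams,
                                      generate_spectra, unambiguous_alphabet)

params = DatasetParams(length_range=(6, 10), tryptic=False,
                       alphabet=unambiguous_alphabet(0.75),
                       noise=NoiseParams.clean())
spectra, truth = generate_spectra(200, params, seed=42)
psms = run_serial(spectra, RunConfig())
hits = sum(p.sequence_str == t.peptide for p, t in zip(psms, truth))
print(f"exact top-1 recovery: {hits}/200 = {hits/200:.1%}")
```

prints `exact top-1 recovery: 199/200 = 99.5%`. With the full 20-residue
alphabet, exact *string* recovery on clean data drops to ~49% purely
because of those isobaric substitutions — the recovered sequences still
have the correct mass ladder.

The scheduler can be exercised on its own against a simulated
heterogeneous pool:

```sh
$ denovopep bench-scheduler --replicates 5 --seed 1
...
median imbalance over 5 replicates: 4.57%
```

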