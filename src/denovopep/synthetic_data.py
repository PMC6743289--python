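"""Seeded generator of ground-truthed peptides and MS/MS spectra.

Emulates tryptic peptides fragmented into singly-charged b/y ion ladders,
with the imperfections real CID spectra show: log-normal intensity
variation, random peak dropout, Gaussian m/z jitter, and uniform
contaminant peaks. Every draw flows from one seed, so a dataset is fully
reproducible; the paired ground-truth table makes every pipeline stage
testable without any external download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import PROTON, STANDARD_RESIDUES, WATER
from .graph_core import ResidueTable, standard_residue_table
from .spectra_io import Spectrum, write_mgf

__all__ = [
    "NoiseParams",
    "DatasetParams",
    "GroundTruthRecord",
    "random_peptide",
    "simulate_spectrum",
    "generate_spectra",
    "generate_dataset",
    "unambiguous_alphabet",
]


@dataclass(frozen=True)
class NoiseParams:
    """Knobs of the spectrum noise model.

    dropout: probability each true fragment peak is missing.
    n_noise_peaks: count of uniform contaminant peaks in (50, parent+50) Da.
    mz_jitter_sd: Gaussian m/z error on true peaks, Da.
    intensity_cv: coefficient of variation of the log-normal peak intensity.
    """

    dropout: float = 0.1
    n_noise_peaks: int = 20
    mz_jitter_sd: float = 0.1
    intensity_cv: float = 0.3

    @classmethod
    def clean(cls) -> "NoiseParams":
        """No dropout, no contaminants, no jitter — the exact theoretical ladder."""
        return cls(dropout=0.0, n_noise_peaks=0, mz_jitter_sd=0.0, intensity_cv=0.0)


#: Contaminant peaks are drawn with this median intensity relative to the
#: (unit) median of true fragment peaks.
NOISE_INTENSITY_SCALE = 0.3


@dataclass(frozen=True)
class DatasetParams:
    """Study conditions of a generated dataset.

    Defaults model a tryptic LTQ-style run whose average peptide length is
    10 residues.
    """

    length_range: tuple[int, int] = (7, 13)
    tryptic: bool = True
    alphabet: tuple[str, ...] | None = None  # None = all 20 standard residues
    charge: int = 2
    #: fixed modifications carried by the simulated peptides; must match the
    #: run configuration or cysteine-containing peptides become unreadable
    fixed_mods: tuple[str, ...] = ("C+57.02146",)
    noise: NoiseParams = field(default_factory=NoiseParams)


@dataclass(frozen=True)
class GroundTruthRecord:
    spectrum_id: str
    peptide: str
    parent_mass: float
    charge: int


def unambiguous_alphabet(fragment_tol: float = 0.75) -> tuple[str, ...]:
    """Standard residues with mass-indistinguishable pairs removed.

    For each set of residues whose masses lie within ``fragment_tol`` of
    one another, only the canonical member is kept (L for the I/L pair,
    otherwise the lexicographically smallest). At the default 0.75 Da this
    drops I (isobaric with L) and Q (0.036 Da from K).
    """
    symbols = sorted(STANDARD_RESIDUES, key=lambda s: (STANDARD_RESIDUES[s], s))
    chains: list[list[str]] = []
    for sym in symbols:
        prev = chains[-1][-1] if chains else None
        if prev is not None and STANDARD_RESIDUES[sym] - STANDARD_RESIDUES[prev] <= fragment_tol:
            chains[-1].append(sym)
        else:
            chains.append([sym])
    kept = ["L" if "L" in chain else min(chain) for chain in chains]
    return tuple(sorted(kept))


def random_peptide(
    length_range: tuple[int, int],
    table: ResidueTable,
    rng: np.random.Generator,
    tryptic: bool = False,
    alphabet: Sequence[str] | None = None,
) -> str:
    """Uniform random peptide with length uniform in ``length_range``.

    Residues are drawn from ``alphabet`` (default: the table's unmodified
    symbols). With ``tryptic`` set, the terminal residue is forced to K or
    R, mimicking trypsin cleavage specificity.
    """
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    if alphabet is None:
        alphabet = tuple(s for s in table.symbols if not s.endswith("*"))
    length = int(rng.integers(lo, hi + 1))
    body = [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]
    if tryptic:
        terminal = [r for r in ("K", "R") if r in alphabet] or ["K", "R"]
        body[-1] = terminal[int(rng.integers(0, len(terminal)))]
    return "".join(body)


def simulate_spectrum(
    p: str,
    table: ResidueTable,
    noise: NoiseParams,
    rng: np.random.Generator,
    spectrum_id: str | None = None,
    charge: int = 2,
) -> Spectrum:
    """Simulate the MS/MS spectrum of peptide ``p`` under the noise model.

    True b/y peaks get log-normal intensities (unit median, CV as
    configured), are dropped independently with the dropout probability,
    and jittered with Gaussian m/z error; contaminant peaks are uniform in
    (50, parent_mass + 50) Da. The precursor m/z is derived from the
    peptide mass at the given charge.
    """
    residue_masses = [table.mass(r) for r in p]
    total = sum(residue_masses)
    parent_mass = total + WATER
    positions: list[float] = []
    prefix = 0.0
    for m in residue_masses:
        prefix += m
        positions.append(prefix + PROTON)                       # b ion
        positions.append(total - (prefix - m) + WATER + PROTON)  # y ion
    positions_arr = np.asarray(sorted(positions))

    if noise.intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise.intensity_cv**2)))
        intensities = rng.lognormal(mean=0.0, sigma=sigma, size=positions_arr.size)
    else:
        intensities = np.ones(positions_arr.size)
    keep = rng.random(positions_arr.size) >= noise.dropout
    mzs = positions_arr[keep]
    intensities = intensities[keep]
    if noise.mz_jitter_sd > 0 and mzs.size:
        mzs = mzs + rng.normal(0.0, noise.mz_jitter_sd, size=mzs.size)

    if noise.n_noise_peaks > 0:
        lo, hi = 50.0, parent_mass + 50.0
        noise_mz = rng.uniform(lo, hi, size=noise.n_noise_peaks)
        if noise.intensity_cv > 0:
            sigma = float(np.sqrt(np.log1p(noise.intensity_cv**2)))
            noise_int = NOISE_INTENSITY_SCALE * rng.lognormal(0.0, sigma, noise.n_noise_peaks)
        else:
            noise_int = np.full(noise.n_noise_peaks, NOISE_INTENSITY_SCALE)
        mzs = np.concatenate([mzs, noise_mz])
        intensities = np.concatenate([intensities, noise_int])

    precursor_mz = (parent_mass + charge * PROTON) / charge
    return Spectrum.from_peaks(
        id=spectrum_id if spectrum_id is not None else p,
        precursor_mz=precursor_mz,
        charge=charge,
        peaks=zip(mzs.tolist(), intensities.tolist()),
        parent_mass=parent_mass,
    )


def generate_spectra(
    n: int, params: DatasetParams, seed: int
) -> tuple[list[Spectrum], list[GroundTruthRecord]]:
    """Generate ``n`` ground-truthed spectra in memory, reproducibly from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    table = standard_residue_table(fixed_mods=params.fixed_mods)
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    spectra: list[Spectrum] = []
    truth: list[GroundTruthRecord] = []
    for i in range(n):
        pep = random_peptide(
            params.length_range, table, rng, tryptic=params.tryptic, alphabet=params.alphabet
        )
        sid = f"synthetic_{i:0{width}d}"
        s = simulate_spectrum(pep, table, params.noise, rng, spectrum_id=sid, charge=params.charge)
        spectra.append(s)
        truth.append(GroundTruthRecord(sid, pep, s.parent_mass, params.charge))
    return spectra, truth


def generate_dataset(
    n: int, params: DatasetParams, seed: int, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``n`` generated spectra as MGF plus a parallel ground-truth TSV.

    Returns the (mgf_path, truth_path) pair. Running twice with the same
    seed produces byte-identical files.
    """
    spectra, truth = generate_spectra(n, params, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mgf_path = out / "synthetic.mgf"
    truth_path = out / "synthetic_truth.tsv"
    write_mgf(spectra, mgf_path)
    with open(truth_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["spectrum_id", "peptide", "parent_mass", "charge"])
        for rec in truth:
            writer.writerow([rec.spectrum_id, rec.peptide, repr(rec.parent_mass), rec.charge])
    return mgf_path, truth_path
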