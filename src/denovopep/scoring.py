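"""Theoretical spectra, binned vectors and cosine PSM scoring.

Each candidate peptide is turned into a theoretical b/y fragment ladder
with unit intensities; both it and the experimental spectrum are binned
on a fixed-width m/z grid and compared by cosine similarity. The
highest-scoring candidate becomes the peptide-spectrum match (PSM)
reported for the spectrum. With non-negative intensities the cosine lies
in [0, 1], and a noise-free ladder scores exactly 1.0 against its own
peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import PROTON, WATER
from .graph_core import CandidatePeptide, ResidueTable
from .spectra_io import Spectrum

__all__ = ["PSM", "BinnedVector", "theoretical_spectrum", "bin_spectrum", "cosine", "score_candidates"]


@dataclass(frozen=True)
class PSM:
    """A scored spectrum ↔ peptide match; the pipeline's output record."""

    spectrum_id: str
    peptide: CandidatePeptide | None
    score: float
    parent_mass: float
    rank: int = 1

    @property
    def sequence_str(self) -> str:
        return "" if self.peptide is None else str(self.peptide)


@dataclass
class BinnedVector:
    """Non-negative intensities on a fixed-width m/z grid."""

    bin_width: float
    values: np.ndarray

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


def theoretical_spectrum(p: Sequence[str], table: ResidueTable) -> Spectrum:
    """Unit-intensity b/y fragment ladder of a peptide.

    Peaks at b_i = prefix_i + proton and y_j = suffix_j + water + proton
    for i, j = 1..len(p); sorted ascending, coincident peaks merged. The
    precursor is reported at charge 2.
    """
    if len(p) == 0:
        raise ValueError("cannot fragment an empty sequence")
    residue_masses = [table.mass(r) for r in p]  # raises KeyError on unknown symbol
    total = sum(residue_masses)
    parent_mass = total + WATER
    peaks: list[tuple[float, float]] = []
    prefix = 0.0
    for m in residue_masses:
        prefix += m
        peaks.append((prefix + PROTON, 1.0))                  # b ion
        peaks.append((total - (prefix - m) + WATER + PROTON, 1.0))  # y ion of the complementary suffix
    precursor_mz = (parent_mass + 2 * PROTON) / 2
    return Spectrum.from_peaks("".join(p), precursor_mz, 2, peaks, parent_mass=parent_mass)


def bin_spectrum(s: Spectrum, bin_width: float, max_mz: float) -> BinnedVector:
    """Accumulate peak intensities into floor(mz / bin_width) bins.

    Peaks above ``max_mz`` are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(max_mz / bin_width)) + 1
    values = np.zeros(n_bins)
    if s.length:
        keep = s.mz <= max_mz
        idx = np.floor(s.mz[keep] / bin_width).astype(int)
        np.add.at(values, idx, s.intensity[keep])
    return BinnedVector(bin_width, values)


def cosine(u: BinnedVector, v: BinnedVector) -> float:
    """Cosine similarity Σuᵢvᵢ / (‖u‖‖v‖); 0 when either vector is all-zero."""
    if u.bin_width != v.bin_width:
        raise ValueError(f"bin_width mismatch: {u.bin_width} vs {v.bin_width}")
    n = min(len(u.values), len(v.values))
    nu, nv = u.norm(), v.norm()
    if nu == 0.0 or nv == 0.0:
        return 0.0
    # identical vectors score exactly 1.0, untouched by rounding
    if len(u.values) == len(v.values) and np.array_equal(u.values, v.values):
        return 1.0
    dot = float(np.dot(u.values[:n], v.values[:n]))
    return min(1.0, max(0.0, dot / (nu * nv)))


def score_candidates(
    s: Spectrum,
    cands: Sequence[CandidatePeptide],
    table: ResidueTable,
    bin_width: float = 0.75,
    sqrt_intensity: bool = True,
) -> PSM:
    """Score every candidate against the spectrum and return the rank-1 PSM.

    The experimental intensities are square-root transformed by default to
    damp dominant peaks (cosine is scale-invariant, so no further
    normalisation is needed). Binning extends to parent_mass + 50 Da. The
    best candidate is chosen by (score descending, sequence ascending) so
    the result does not depend on candidate input order; with no
    candidates an empty PSM with score 0 is returned.
    """
    if not cands:
        return PSM(s.id, None, 0.0, s.parent_mass)
    max_mz = s.parent_mass + 50.0
    exp = s
    if sqrt_intensity and s.length:
        exp = Spectrum(s.id, s.precursor_mz, s.charge, s.parent_mass, s.mz, np.sqrt(s.intensity))
    exp_binned = bin_spectrum(exp, bin_width, max_mz)
    best: tuple[float, tuple[str, ...]] | None = None
    best_cand: CandidatePeptide | None = None
    for cand in cands:
        theo = theoretical_spectrum(cand.sequence, table)
        sc = cosine(exp_binned, bin_spectrum(theo, bin_width, max_mz))
        key = (-sc, cand.sequence)
        if best is None or key < best:
            best = key
            best_cand = cand
    assert best is not None and best_cand is not None
    return PSM(s.id, best_cand, -best[0], s.parent_mass)
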