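"""Reading and writing MS/MS spectra and result tables.

Spectra travel through the pipeline as :class:`Spectrum` objects: a
precursor description plus a peak list kept strictly ascending in m/z.
Input is Mascot Generic Format (MGF); results are written as a
tab-separated table.

The MGF dialect accepted here: ``BEGIN IONS``/``END IONS`` blocks with
``TITLE``, ``PEPMASS``, ``CHARGE`` and ``RTINSECONDS`` headers (unknown
headers are ignored); peak lines are whitespace-separated ``mz intensity``
with intensity defaulting to 1.0 when absent; ``CHARGE`` defaults to 2
when the header is missing. The reader is written out longhand rather than
delegated to :mod:`pyteomics.mgf`, whose reader silently desynchronises
the m/z and intensity arrays when a peak line carries no intensity.
Writing goes through :func:`pyteomics.mgf.write`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pyteomics import mgf as _pyteomics_mgf

from .constants import PROTON

__all__ = [
    "Peak",
    "Spectrum",
    "MGFParseError",
    "read_mgf",
    "write_mgf",
    "parent_mass_of",
    "effective_peaks",
    "write_results",
    "read_results",
]

#: Two peaks closer than this in m/z are considered the same peak and
#: merged by summing their intensities.
MZ_MERGE_EPS = 1e-6


class Peak(NamedTuple):
    """One centroided fragment peak: m/z in Da and an arbitrary-unit intensity."""

    mz: float
    intensity: float


class MGFParseError(ValueError):
    """Raised when an MGF block violates the expected dialect."""


@dataclass
class Spectrum:
    """A single MS/MS scan.

    Attributes
    ----------
    id:
        Text identifier (the MGF ``TITLE``, or the block ordinal).
    precursor_mz:
        Measured precursor m/z in Da.
    charge:
        Precursor charge state (positive integer).
    parent_mass:
        Neutral mass of the intact peptide in Da, derived from
        ``precursor_mz`` and ``charge``.
    mz, intensity:
        Parallel arrays holding the peak list, strictly ascending in m/z.
    """

    id: str
    precursor_mz: float
    charge: int
    parent_mass: float
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and (np.diff(self.mz) <= 0).any():
            raise ValueError(f"spectrum {self.id!r}: peaks not strictly ascending in m/z")
        if self.parent_mass <= 0:
            raise ValueError(f"spectrum {self.id!r}: parent_mass must be positive")

    @classmethod
    def from_peaks(
        cls,
        id: str,
        precursor_mz: float,
        charge: int,
        peaks: Iterable[tuple[float, float]],
        parent_mass: float | None = None,
    ) -> "Spectrum":
        """Build a spectrum from unordered peaks, sorting and merging duplicates.

        Peaks within :data:`MZ_MERGE_EPS` Da of each other collapse to a
        single peak whose intensity is the sum. ``parent_mass`` defaults to
        the neutral mass implied by the precursor.
        """
        pk = sorted(peaks)
        mzs: list[float] = []
        ints: list[float] = []
        for mz, inten in pk:
            if mzs and mz - mzs[-1] <= MZ_MERGE_EPS:
                ints[-1] += inten
            else:
                mzs.append(mz)
                ints.append(inten)
        if parent_mass is None:
            parent_mass = parent_mass_of(precursor_mz, charge)
        return cls(id, precursor_mz, charge, parent_mass, np.array(mzs), np.array(ints))

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def length(self) -> int:
        """Number of peaks; the quantity batch scheduling sorts on."""
        return int(self.mz.size)


def parent_mass_of(precursor_mz: float, charge: int) -> float:
    """Neutral peptide mass M from a precursor m/z and charge.

    The observed ion is ``[M + charge * H+] / charge``, so
    ``M = precursor_mz * charge - charge * PROTON``.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return precursor_mz * charge - charge * PROTON


def _parse_charge(text: str) -> int:
    text = text.strip().split()[0] if text.strip() else ""
    text = text.rstrip("+")
    if text.startswith("-") or text.endswith("-"):
        raise MGFParseError(f"negative charge unsupported: {text!r}")
    return int(text)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read every ``BEGIN IONS`` block of an MGF file, in file order.

    Raises
    ------
    MGFParseError
        If a block lacks ``PEPMASS`` or contains a malformed line; the
        message names the offending (1-based) block.
    OSError
        If the path cannot be read.
    """
    spectra: list[Spectrum] = []
    in_block = False
    block_no = 0
    title: str | None = None
    pepmass: float | None = None
    charge: int | None = None
    peaks: list[tuple[float, float]] = []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                block_no += 1
                title, pepmass, charge, peaks = None, None, None, []
                continue
            if line == "END IONS":
                if not in_block:
                    raise MGFParseError(f"line {lineno}: END IONS outside a block")
                if pepmass is None:
                    raise MGFParseError(f"block {block_no}: missing PEPMASS")
                spectra.append(
                    Spectrum.from_peaks(
                        id=title if title is not None else str(block_no),
                        precursor_mz=pepmass,
                        charge=charge if charge is not None else 2,
                        peaks=peaks,
                    )
                )
                in_block = False
                continue
            if not in_block:
                continue  # headers outside blocks (e.g. COM=) are ignored
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.strip().upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    try:
                        pepmass = float(value.split()[0])
                    except (ValueError, IndexError) as exc:
                        raise MGFParseError(f"block {block_no}: bad PEPMASS {value!r}") from exc
                elif key == "CHARGE":
                    try:
                        charge = _parse_charge(value)
                    except ValueError as exc:
                        raise MGFParseError(f"block {block_no}: bad CHARGE {value!r}") from exc
                # all other headers ignored
                continue
            fields = line.split()
            try:
                mz = float(fields[0])
                inten = float(fields[1]) if len(fields) > 1 else 1.0
            except ValueError as exc:
                raise MGFParseError(f"block {block_no}: bad peak line {line!r}") from exc
            peaks.append((mz, inten))

    if in_block:
        raise MGFParseError(f"block {block_no}: unterminated (missing END IONS)")
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF via pyteomics, one block per spectrum, in order."""
    entries = [
        {
            "params": {"title": s.id, "pepmass": s.precursor_mz, "charge": s.charge},
            "m/z array": s.mz,
            "intensity array": s.intensity,
        }
        for s in spectra
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _pyteomics_mgf.write(entries, fh)


def effective_peaks(s: Spectrum, window: float = 100.0, keep_per_window: int = 6) -> Spectrum:
    """Reduce a raw peak list to the effective peak set used for graph building.

    In every non-overlapping m/z window of the stated width (starting at 0),
    only the ``keep_per_window`` most intense peaks survive. Peak order and
    every other field are preserved; applying the filter twice changes
    nothing.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if keep_per_window < 1:
        raise ValueError("keep_per_window must be >= 1")
    if s.length == 0:
        return s
    bins = np.floor(s.mz / window).astype(int)
    keep = np.zeros(s.length, dtype=bool)
    for b in np.unique(bins):
        idx = np.nonzero(bins == b)[0]
        if idx.size <= keep_per_window:
            keep[idx] = True
        else:
            # ties broken toward lower m/z for determinism (stable sort)
            order = np.argsort(-s.intensity[idx], kind="stable")
            keep[idx[order[:keep_per_window]]] = True
    return Spectrum(s.id, s.precursor_mz, s.charge, s.parent_mass, s.mz[keep], s.intensity[keep])


def write_results(psms: Sequence, path: str | Path) -> None:
    """Write PSMs as a TSV with columns spectrum_id, peptide, score, parent_mass."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["spectrum_id", "peptide", "score", "parent_mass"])
        for psm in psms:
            writer.writerow(
                [psm.spectrum_id, psm.sequence_str, repr(psm.score), repr(psm.parent_mass)]
            )


def read_results(path: str | Path) -> list[dict]:
    """Re-read a results TSV into plain records (inverse of :func:`write_results`)."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                {
                    "spectrum_id": row["spectrum_id"],
                    "peptide": row["peptide"],
                    "score": float(row["score"]),
                    "parent_mass": float(row["parent_mass"]),
                }
            )
    return out
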