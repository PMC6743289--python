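"""Run configuration: sequencing parameters plus scheduling knobs.

Defaults follow common practice for CID tryptic data: 2 Da precursor
tolerance, 0.75 Da fragment tolerance, fixed carbamidomethyl-cysteine
(C+57.02146) and variable methionine oxidation (M+15.99491), tag length 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .graph_core import ResidueTable, standard_residue_table

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # sequencing parameters
    precursor_tol: float = 2.0       # Da, tolerance on the parent residue mass
    fragment_tol: float = 0.75       # Da, tolerance on fragment/edge masses
    merge_tol: float | None = None   # Da, node clustering radius; default fragment_tol/2
    fixed_mods: tuple[str, ...] = ("C+57.02146",)
    variable_mods: tuple[str, ...] = ("M+15.99491",)
    tag_length: int = 6
    tag_filter: bool = False         # optional tag pre-filter on candidates
    max_length: int = 30             # residues per candidate
    max_candidates: int = 10_000     # enumeration cap per spectrum
    window: float = 100.0            # Da, effective-peak window width
    keep_per_window: int = 6         # peaks kept per window
    bin_width: float | None = None   # Da, scoring grid; default fragment_tol
    sqrt_intensity: bool = True
    # scheduling knobs
    workers: int = 4
    groups_per_chunk: int = 2
    reprobe_every: int = 0           # re-probe after this many chunks; 0 = never
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.groups_per_chunk < 1:
            raise ValueError("groups_per_chunk must be >= 1")

    @property
    def effective_merge_tol(self) -> float:
        return self.fragment_tol / 2.0 if self.merge_tol is None else self.merge_tol

    @property
    def effective_bin_width(self) -> float:
        return self.fragment_tol if self.bin_width is None else self.bin_width

    def residue_table(self) -> ResidueTable:
        return standard_residue_table(self.fixed_mods, self.variable_mods)


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Flags/overrides win over file values; unknown keys are rejected.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("fixed_mods", "variable_mods"):
        if key in values and values[key] is not None:
            values[key] = tuple(values[key])
    return RunConfig(**values)
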