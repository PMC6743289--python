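"""Residue chemistry, spectrum-graph construction and candidate enumeration.

The spectrum graph is a DAG over *prefix residue masses* (PRM): each
fragment peak is interpreted both as a b ion (N-terminal prefix plus a
proton) and as a y ion (C-terminal suffix plus water and a proton), and
both interpretations are mapped onto the common prefix-mass axis. Nodes
are clustered mass values on that axis, always including the source (0)
and the sink (parent residue mass, i.e. neutral mass minus water); an
edge connects two nodes whose mass difference matches an amino-acid
residue mass within the fragment tolerance. A candidate peptide is a
source-to-sink path whose residue masses sum to the parent residue mass
within the precursor tolerance.

Only singly-charged b and y ions are interpreted — the dominant series
under CID fragmentation. Isobaric residues collapse onto one canonical
edge label (I/L is reported as L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import PROTON, STANDARD_RESIDUES, WATER
from .spectra_io import Spectrum

__all__ = [
    "ResidueTable",
    "SpectrumGraph",
    "CandidatePeptide",
    "standard_residue_table",
    "interpret_peaks",
    "build_graph",
    "graph_from_nodes",
    "enumerate_candidates",
    "brute_force_candidates",
    "extract_tags",
]

_MOD_RE = re.compile(r"^([A-Z])([+-]\d+(?:\.\d+)?)$")

#: Well-known modification deltas, so configs may say "C+57" for
#: carbamidomethylation and "M+16" for oxidation and still get the
#: monoisotopic value.
_NOMINAL_DELTAS = {57.0: 57.02146, 16.0: 15.99491}


@dataclass(frozen=True)
class ResidueTable:
    """Mapping from residue symbols to monoisotopic masses, mods folded in.

    Fixed modifications shift the base residue mass in place; each variable
    modification adds a starred symbol (``M*`` = M + delta) alongside the
    unmodified one.
    """

    masses: dict[str, float]
    fixed_mods: dict[str, float] = field(default_factory=dict)
    variable_mods: dict[str, float] = field(default_factory=dict)

    def mass(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise KeyError(f"unknown residue symbol {symbol!r}") from None

    def sequence_mass(self, sequence: Sequence[str]) -> float:
        """Total residue mass of a sequence (no water: this is M − H2O)."""
        return float(sum(self.mass(r) for r in sequence))

    @property
    def symbols(self) -> list[str]:
        return sorted(self.masses)

    @property
    def min_mass(self) -> float:
        return min(self.masses.values())

    @property
    def max_mass(self) -> float:
        return max(self.masses.values())

    def edge_alphabet(self) -> list[tuple[str, float]]:
        """(symbol, mass) pairs with exact-isobaric duplicates collapsed.

        Residues sharing a mass produce indistinguishable edges; one
        canonical label is kept per mass (L wins over I, otherwise the
        lexicographically smallest symbol). Sorted by mass for
        deterministic edge ordering.
        """
        by_mass: dict[float, list[str]] = {}
        for sym, m in self.masses.items():
            by_mass.setdefault(m, []).append(sym)
        out = []
        for m, syms in by_mass.items():
            if "L" in syms:
                out.append(("L", m))
            else:
                out.append((min(syms), m))
        return sorted(out, key=lambda t: (t[1], t[0]))


def _parse_mod(spec: str) -> tuple[str, float]:
    m = _MOD_RE.match(spec.strip())
    if not m:
        raise ValueError(f"malformed modification spec {spec!r}; expected e.g. 'C+57.02146'")
    residue, delta = m.group(1), float(m.group(2))
    if residue not in STANDARD_RESIDUES:
        raise ValueError(f"unknown residue symbol {residue!r} in mod spec {spec!r}")
    delta = _NOMINAL_DELTAS.get(abs(delta), abs(delta)) * (1 if delta > 0 else -1)
    return residue, delta


def standard_residue_table(
    fixed_mods: Iterable[str] = (), variable_mods: Iterable[str] = ()
) -> ResidueTable:
    """The 20 standard residues with fixed/variable modifications applied.

    Mod specs look like ``C+57.02146`` (fixed carbamidomethyl-cysteine) or
    ``M+15.99491`` (variable methionine oxidation); nominal integer deltas
    (``C+57``, ``M+16``) are resolved to their monoisotopic values.
    """
    masses = dict(STANDARD_RESIDUES)
    fixed: dict[str, float] = {}
    variable: dict[str, float] = {}
    for spec in fixed_mods:
        residue, delta = _parse_mod(spec)
        masses[residue] = STANDARD_RESIDUES[residue] + delta
        fixed[residue] = delta
    for spec in variable_mods:
        residue, delta = _parse_mod(spec)
        starred = residue + "*"
        if starred in masses:
            raise ValueError(f"duplicate variable modification for {residue!r}")
        masses[starred] = masses[residue] + delta
        variable[residue] = delta
    return ResidueTable(masses, fixed, variable)


@dataclass
class SpectrumGraph:
    """DAG over prefix masses with residue-labelled edges.

    ``nodes`` is sorted ascending and always contains 0 (source) and
    ``sink`` = parent residue mass. ``edges[u]`` lists ``(v, symbol)``
    successors, ordered by target mass then label. ``node_support`` holds
    the summed intensity of the peaks supporting each node.
    """

    nodes: np.ndarray
    edges: list[list[tuple[int, str]]]
    node_support: np.ndarray
    sink_mass: float

    @property
    def source_index(self) -> int:
        return 0

    @property
    def sink_index(self) -> int:
        return len(self.nodes) - 1

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges)


@dataclass(frozen=True)
class CandidatePeptide:
    """A source→sink path: residue symbols, total residue mass, node indices."""

    sequence: tuple[str, ...]
    mass: float
    path: tuple[int, ...]

    def __str__(self) -> str:
        return "".join(self.sequence)


def interpret_peaks(s: Spectrum, table: ResidueTable) -> list[tuple[float, float]]:
    """Map each peak to prefix-mass interpretations, as (mass, support) pairs.

    Each peak contributes a b interpretation (mz − proton) and a y
    interpretation (M + proton − mz, M the neutral parent mass); values
    outside the open interval (0, sink) are discarded. The source (0) and
    sink (M − water) are always appended with zero support.
    """
    sink = s.parent_mass - WATER
    out: list[tuple[float, float]] = []
    for mz, inten in zip(s.mz, s.intensity):
        for prefix in (mz - PROTON, s.parent_mass + PROTON - mz):
            if 0.0 < prefix < sink:
                out.append((float(prefix), float(inten)))
    out.append((0.0, 0.0))
    out.append((float(sink), 0.0))
    return out


def _cluster_interpretations(
    interpretations: list[tuple[float, float]], sink: float, merge_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage clustering of prefix masses at ``merge_tol``.

    Clusters are replaced by their support-weighted mean (plain mean when a
    cluster carries no intensity). A cluster containing the source or sink
    snaps to that exact anchor so the graph ends never drift or vanish.
    """
    pts = sorted(interpretations)
    positions: list[float] = []
    supports: list[float] = []
    i = 0
    n = len(pts)
    while i < n:
        j = i + 1
        while j < n and pts[j][0] - pts[j - 1][0] <= merge_tol:
            j += 1
        cluster = pts[i:j]
        masses = np.array([c[0] for c in cluster])
        weights = np.array([c[1] for c in cluster])
        anchors = [m for m in (0.0, sink) if any(abs(c[0] - m) < 1e-12 for c in cluster)]
        if anchors:
            # a cluster may straddle both anchors only for absurdly small sinks
            for a in anchors:
                positions.append(a)
                supports.append(float(weights.sum()) / len(anchors))
        elif weights.sum() > 0:
            positions.append(float(np.average(masses, weights=weights)))
            supports.append(float(weights.sum()))
        else:
            positions.append(float(masses.mean()))
            supports.append(0.0)
        i = j
    order = np.argsort(positions, kind="stable")
    return np.asarray(positions)[order], np.asarray(supports)[order]


def build_graph(
    s: Spectrum,
    table: ResidueTable,
    fragment_tol: float = 0.75,
    merge_tol: float | None = None,
) -> SpectrumGraph:
    """Construct the spectrum graph for one spectrum.

    Peak interpretations are clustered at ``merge_tol`` (default half the
    fragment tolerance) so that coincident b/y evidence fuses into a single
    node; an edge (u, v, r) exists iff |(node_v − node_u) − mass(r)| ≤
    ``fragment_tol``. Node order (ascending mass) and edge order are
    deterministic, so graph construction is invariant to the order in
    which peaks were listed.
    """
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be positive")
    if merge_tol is None:
        merge_tol = fragment_tol / 2.0
    sink = s.parent_mass - WATER
    nodes, support = _cluster_interpretations(interpret_peaks(s, table), sink, merge_tol)
    return _assemble(nodes, support, sink, table, fragment_tol)


def graph_from_nodes(
    node_masses: Sequence[float],
    sink: float,
    table: ResidueTable,
    fragment_tol: float,
    node_support: Sequence[float] | None = None,
) -> SpectrumGraph:
    """Build a graph directly from prefix masses (no peak interpretation).

    Intended for synthetic instances and tests; 0 and ``sink`` are added if
    absent.
    """
    masses = sorted(set(float(m) for m in node_masses) | {0.0, float(sink)})
    nodes = np.asarray(masses)
    if node_support is None:
        support = np.zeros(len(nodes))
    else:
        by_mass = {float(m): float(w) for m, w in zip(node_masses, node_support)}
        support = np.array([by_mass.get(m, 0.0) for m in masses])
    return _assemble(nodes, support, float(sink), table, fragment_tol)


def _assemble(
    nodes: np.ndarray,
    support: np.ndarray,
    sink: float,
    table: ResidueTable,
    fragment_tol: float,
) -> SpectrumGraph:
    alphabet = table.edge_alphabet()
    n = len(nodes)
    edges: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for u in range(n):
        for sym, m in alphabet:
            lo = nodes[u] + m - fragment_tol
            hi = nodes[u] + m + fragment_tol
            left = int(np.searchsorted(nodes, lo, side="left"))
            right = int(np.searchsorted(nodes, hi, side="right"))
            for v in range(left, right):
                if v != u and nodes[v] > nodes[u]:
                    edges[u].append((v, sym))
        edges[u].sort(key=lambda t: (nodes[t[0]], t[1]))
    keep = _path_nodes(n, edges)
    if len(keep) < n:
        remap = {old: new for new, old in enumerate(keep)}
        nodes = nodes[keep]
        support = support[keep]
        edges = [
            [(remap[v], sym) for v, sym in edges[old] if v in remap] for old in keep
        ]
    return SpectrumGraph(nodes, edges, support, sink)


def _path_nodes(n: int, edges: list[list[tuple[int, str]]]) -> list[int]:
    """Indices of nodes lying on some source→sink path (ends always kept).

    A candidate peptide is a full source→sink path, so stray mass
    interpretations reachable from neither end can never contribute;
    dropping them shrinks the enumeration without changing its output.
    """
    fwd = np.zeros(n, dtype=bool)
    fwd[0] = True
    for u in range(n):  # edges go low->high, one ascending pass suffices
        if fwd[u]:
            for v, _ in edges[u]:
                fwd[v] = True
    bwd = np.zeros(n, dtype=bool)
    bwd[n - 1] = True
    for u in range(n - 1, -1, -1):
        if not bwd[u]:
            bwd[u] = any(bwd[v] for v, _ in edges[u])
    keep = fwd & bwd
    keep[0] = keep[n - 1] = True
    return [i for i in range(n) if keep[i]]


def enumerate_candidates(
    g: SpectrumGraph,
    table: ResidueTable,
    precursor_tol: float = 2.0,
    max_length: int = 30,
    cap: int = 10_000,
    tags: set[str] | None = None,
    tag_length: int = 6,
) -> list[CandidatePeptide]:
    """Depth-first enumeration of source→sink paths, i.e. candidate peptides.

    A path is emitted when it reaches the sink node with at most
    ``max_length`` edges and its residue-mass sum is within
    ``precursor_tol`` of the sink mass. Branches are pruned when the
    remaining mass cannot be bridged by any residue count that still fits.
    Exploration stops once ``cap`` candidates have been collected (the DFS
    order is deterministic); the survivors are then ordered by descending
    path node-support, ties broken by lexicographic sequence.

    When ``tags`` is given, a candidate must contain at least one of the
    tag strings (candidates shorter than ``tag_length`` are kept).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    sink_idx = g.sink_index
    sink = g.sink_mass
    min_res, max_res = table.min_mass, table.max_mass
    out: list[CandidatePeptide] = []
    seq: list[str] = []
    path: list[int] = [g.source_index]
    mass = 0.0

    def dfs(u: int) -> bool:
        """Returns False once the cap is hit to unwind the recursion."""
        nonlocal mass
        if u == sink_idx:
            if abs(mass - sink) <= precursor_tol:
                if tags is None or len(seq) < tag_length or _contains_tag(seq, tags, tag_length):
                    out.append(CandidatePeptide(tuple(seq), mass, tuple(path)))
                    if len(out) >= cap:
                        return False
            return True
        hops_left = max_length - len(seq)
        if hops_left <= 0:
            return True
        remaining = sink - mass
        if remaining > hops_left * max_res + precursor_tol:
            return True  # cannot climb to the sink in the hops left
        if remaining < min_res - precursor_tol:
            return True  # overshot: even one more residue is too heavy
        for v, sym in g.edges[u]:
            seq.append(sym)
            path.append(v)
            mass += table.mass(sym)
            alive = dfs(v)
            mass -= table.mass(sym)
            path.pop()
            seq.pop()
            if not alive:
                return False
        return True

    dfs(g.source_index)
    out.sort(key=lambda c: (-_path_support(g, c.path), c.sequence))
    return out


def _path_support(g: SpectrumGraph, path: tuple[int, ...]) -> float:
    return float(g.node_support[list(path)].sum())


def _contains_tag(seq: list[str], tags: set[str], tag_length: int) -> bool:
    s = "".join(seq)
    return any(s[i : i + tag_length] in tags for i in range(len(s) - tag_length + 1))


def brute_force_candidates(
    table: ResidueTable,
    target_mass: float,
    tol: float,
    max_length: int,
) -> set[tuple[str, ...]]:
    """All sequences of ≤ ``max_length`` residues whose mass sum hits the target.

    Exhaustive test oracle — exponential in ``max_length``, refused above 6.
    Uses the same collapsed edge alphabet as the graph so isobaric residues
    appear once, under their canonical symbol.
    """
    if max_length > 6:
        raise ValueError("brute_force_candidates is exponential; max_length must be <= 6")
    alphabet = table.edge_alphabet()
    out: set[tuple[str, ...]] = set()

    def extend(prefix: tuple[str, ...], mass: float) -> None:
        if abs(mass - target_mass) <= tol:
            out.add(prefix)
        if len(prefix) >= max_length:
            return
        for sym, m in alphabet:
            if mass + m <= target_mass + tol:
                extend(prefix + (sym,), mass + m)

    extend((), 0.0)
    return out


def extract_tags(g: SpectrumGraph, tag_length: int) -> list[str]:
    """All residue strings along paths of exactly ``tag_length`` edges.

    Walks every node of the graph; the result is deduplicated and
    lexicographically sorted. Tags are the short, high-confidence
    subsequences used to pre-filter candidate enumeration.
    """
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    found: set[str] = set()

    def walk(u: int, acc: list[str]) -> None:
        if len(acc) == tag_length:
            found.add("".join(acc))
            return
        for v, sym in g.edges[u]:
            acc.append(sym)
            walk(v, acc)
            acc.pop()

    for u in range(len(g.nodes)):
        walk(u, [])
    return sorted(found)
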