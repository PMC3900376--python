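"""Thresholded force-difference networks and pathway extraction.

Residues become nodes; an edge joins residues u,v when any atom pair
spanning them has |dF_ij| strictly above the cutoff, weighted by the
maximum such |dF_ij| (pN).  The cutoff is chosen by scanning: the
recommended value is the largest grid point at which every source
residue reaches every target residue through the largest connected
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .fda_stats import ForceDifference

#: default force-difference cutoff, pN
DEFAULT_CUTOFF_PN = 90.0

#: cap on enumerated shortest paths per source/target pair
MAX_PATHS_PER_PAIR = 100


@dataclass
class ForceGraph:
    graph: nx.Graph
    cutoff_pN: float

    @property
    def nodes(self) -> Set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[int, int, float]]:
        return [
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class CutoffScanRow:
    cutoff_pN: float
    vertex_count: int
    n_components: int
    connected: bool


@dataclass
class CutoffScanResult:
    rows: List[CutoffScanRow]
    recommended_cutoff_pN: Optional[float]

    @property
    def broken_path(self) -> bool:
        return self.recommended_cutoff_pN is None


@dataclass
class PathwayResult:
    paths: List[List[int]]  # ordered residue chains, source first
    unreachable: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def hop_counts(self) -> List[int]:
        return [len(p) - 1 for p in self.paths]

    @property
    def residues_on_paths(self) -> Set[int]:
        return {r for p in self.paths for r in p}


def build_graph(
    diff: ForceDifference,
    residue_of: Mapping[int, int],
    cutoff_pN: float = DEFAULT_CUTOFF_PN,
    include_residues: Optional[Iterable[int]] = None,
    min_seq_separation: int = 0,
) -> ForceGraph:
    """Residue graph of force differences strictly above the cutoff.

    ``include_residues`` restricts the node universe (e.g. protein
    only); ``min_seq_separation`` optionally drops |u - v| < s pairs.
    """
    if cutoff_pN < 0:
        raise ValueError("cutoff must be non-negative")
    allowed = set(include_residues) if include_residues is not None else None
    best: Dict[Tuple[int, int], float] = {}
    for (i, j), val in diff.items():
        u, v = residue_of[i], residue_of[j]
        if u == v:
            continue
        if allowed is not None and (u not in allowed or v not in allowed):
            continue
        if abs(u - v) < min_seq_separation:
            continue
        key = (min(u, v), max(u, v))
        mag = abs(val)
        if mag > cutoff_pN and mag > best.get(key, 0.0):
            best[key] = mag
    graph = nx.Graph()
    for (u, v), w in best.items():
        graph.add_edge(u, v, weight=w)
    return ForceGraph(graph=graph, cutoff_pN=cutoff_pN)


def largest_component(fg: ForceGraph) -> Tuple[ForceGraph, int]:
    """Largest connected component; ties broken by smallest member node."""
    comps = list(nx.connected_components(fg.graph))
    if not comps:
        return ForceGraph(nx.Graph(), fg.cutoff_pN), 0
    comps.sort(key=lambda c: (-len(c), min(c)))
    sub = fg.graph.subgraph(comps[0]).copy()
    return ForceGraph(sub, fg.cutoff_pN), sub.number_of_nodes()


def scan_cutoffs(
    diff: ForceDifference,
    residue_of: Mapping[int, int],
    sources: Sequence[int],
    targets: Sequence[int],
    cutoff_grid: Sequence[float],
    include_residues: Optional[Iterable[int]] = None,
    min_seq_separation: int = 0,
) -> CutoffScanResult:
    """Scan cutoffs and recommend the largest keeping sources connected
    to targets through the largest component."""
    if not len(cutoff_grid) or not len(sources) or not len(targets):
        raise ValueError("cutoff grid, sources and targets must be nonempty")
    rows: List[CutoffScanRow] = []
    recommended: Optional[float] = None
    for cutoff in sorted(cutoff_grid):
        fg = build_graph(
            diff,
            residue_of,
            cutoff_pN=cutoff,
            include_residues=include_residues,
            min_seq_separation=min_seq_separation,
        )
        lcc, count = largest_component(fg)
        connected = bool(
            count
            and all(s in lcc.nodes for s in sources)
            and all(t in lcc.nodes for t in targets)
        )
        rows.append(
            CutoffScanRow(
                cutoff_pN=float(cutoff),
                vertex_count=count,
                n_components=nx.number_connected_components(fg.graph),
                connected=connected,
            )
        )
        if connected:
            recommended = float(cutoff)
    return CutoffScanResult(rows=rows, recommended_cutoff_pN=recommended)


def extract_pathways(
    fg: ForceGraph, sources: Sequence[int], targets: Sequence[int]
) -> PathwayResult:
    """All shortest paths (hop metric) from each source to its nearest
    reachable target(s); unreachable source/target pairs listed apart."""
    paths: List[List[int]] = []
    unreachable: List[Tuple[int, int]] = []
    graph = fg.graph
    target_set = [t for t in targets]
    for s in sources:
        if s not in graph:
            unreachable.extend((s, t) for t in target_set)
            continue
        lengths = nx.single_source_shortest_path_length(graph, s)
        reachable = {t: lengths[t] for t in target_set if t in lengths}
        for t in target_set:
            if t not in reachable:
                unreachable.append((s, t))
        if not reachable:
            continue
        nearest = min(reachable.values())
        for t, dist in reachable.items():
            if dist != nearest:
                continue
            for n, path in enumerate(nx.all_shortest_paths(graph, s, t)):
                if n >= MAX_PATHS_PER_PAIR:
                    break
                paths.append(list(path))
    return PathwayResult(paths=paths, unreachable=unreachable)
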