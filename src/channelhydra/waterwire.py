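"""Hydrogen-bond graphs over waters and relay atoms, and water-wire detection.

A *water wire* is a per-frame path through the hydrogen-bond graph — nodes
are water oxygens plus the side-chain N/O atoms of configured relay residues,
edges join nodes within the H-bond cutoff — linking a bulk source region to a
target atom (the c-ring carboxylate analogue). Path optimality is hop count,
matching the Grotthuss picture of discrete proton hops, not geometric length.

For frames without a wire the break is attributed to the relay residue
nearest the largest gap: the closest approach between the source-connected
component and the target-connected component.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .contacts import DEFAULT_HBOND_CUTOFF
from .errors import DomainError
from .trajio import Selection, Trajectory


@dataclass
class HBondGraph:
    """Hydrogen-bond graph at one frame.

    ``nodes`` are global atom indices; ``edges`` are unordered index pairs
    with min-image distance ≤ cutoff; ``water_nodes`` flags which nodes are
    water oxygens.
    """

    frame: int
    nodes: np.ndarray
    edges: list[tuple[int, int, float]]
    water_nodes: frozenset
    cutoff: float

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {int(n): [] for n in self.nodes}
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        for n in adj:
            adj[n].sort()
        return adj


@dataclass
class WirePath:
    frame: int
    nodes: list[int]  # ordered, source → target
    n_water_nodes: int
    relay_residues: list[str]

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1


@dataclass
class WireSummary:
    """Continuity statistics of a water wire over a trajectory."""

    continuity_fraction: float
    exists: np.ndarray  # per-analyzed-frame flags
    path_lengths: Counter  # n_edges -> frame count, over frames with a wire
    breakpoint_counts: Counter  # relay residue label -> broken-frame count
    frames: np.ndarray
    cutoff: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "continuity_fraction": self.continuity_fraction,
                    "cutoff": self.cutoff,
                    "n_frames": int(len(self.exists)),
                    "path_length_distribution":
                        {str(k): int(v) for k, v in sorted(self.path_lengths.items())},
                    "breakpoint_counts":
                        dict(sorted(self.breakpoint_counts.items())),
                },
                fh, indent=1,
            )


def build_hbond_graph(traj_or_coords, frame, water_sel: Selection,
                      relay_sel: Selection,
                      cutoff: float = DEFAULT_HBOND_CUTOFF,
                      box=None) -> HBondGraph:
    """H-bond graph for one frame.

    ``traj_or_coords`` may be a :class:`Trajectory` (with ``frame`` an index)
    or a coordinate array (with ``box`` given explicitly).
    """
    if np.intersect1d(water_sel.indices, relay_sel.indices).size:
        raise DomainError("water and relay selections must be disjoint")
    if isinstance(traj_or_coords, Trajectory):
        coords, box = traj_or_coords.frame(frame)
    else:
        coords = np.asarray(traj_or_coords, dtype=float)
        if box is None:
            raise DomainError("box is required with raw coordinates")
    nodes = np.union1d(water_sel.indices, relay_sel.indices)
    edges = geometry.pairs_within_cutoff(coords, box, nodes, nodes, cutoff)
    return HBondGraph(frame=frame, nodes=nodes, edges=edges,
                      water_nodes=frozenset(int(i) for i in water_sel.indices),
                      cutoff=cutoff)


def _bfs_path(adj: dict[int, list[int]], sources, targets) -> list[int] | None:
    """Fewest-edges path from any source to any target.

    Deterministic: neighbors are expanded in ascending index order, the
    reached target with the smallest (distance, index) wins, and parents are
    the first (smallest-index-at-minimal-depth) discoverers.
    """
    sources = sorted({int(s) for s in sources} & adj.keys())
    targets = {int(t) for t in targets} & adj.keys()
    if not sources or not targets:
        return None
    at_source = sorted(set(sources) & targets)
    if at_source:
        return [at_source[0]]
    parent: dict[int, int | None] = {s: None for s in sources}
    frontier = sources
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    nxt.append(v)
        found = sorted(set(nxt) & targets)
        if found:
            path = [found[0]]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            return path[::-1]
        frontier = sorted(set(nxt))
    return None


def find_wire(graph: HBondGraph, source_nodes, target_nodes,
              topology=None) -> WirePath | None:
    """Shortest (fewest edges) path from any source node to any target node
    of the graph, or None when no path exists."""
    if len(list(source_nodes)) == 0 or len(list(target_nodes)) == 0:
        raise DomainError("source and target node sets must be non-empty")
    adj = graph.adjacency()
    path = _bfs_path(adj, source_nodes, target_nodes)
    if path is None:
        return None
    n_water = sum(1 for n in path if n in graph.water_nodes)
    relays = []
    if topology is not None:
        atoms = topology.atoms
        for n in path:
            if n not in graph.water_nodes:
                label = (f"{atoms['chain_id'].iat[n]}"
                         f"{atoms['residue_name'].iat[n]}"
                         f"{atoms['residue_id'].iat[n]}")
                if label not in relays:
                    relays.append(label)
    return WirePath(frame=graph.frame, nodes=[int(n) for n in path],
                    n_water_nodes=n_water, relay_residues=relays)


def _relay_labels(topology, relay_sel: Selection) -> dict[int, str]:
    atoms = topology.atoms
    return {
        int(i): (f"{atoms['chain_id'].iat[i]}{atoms['residue_name'].iat[i]}"
                 f"{atoms['residue_id'].iat[i]}")
        for i in relay_sel.indices
    }


def wire_continuity(traj: Trajectory, entrance_sel: Selection,
                    source_radius: float, target_sel: Selection,
                    relay_sel: Selection, water_sel: Selection,
                    cutoff: float = DEFAULT_HBOND_CUTOFF,
                    stride: int = 1) -> WireSummary:
    """Per-frame wire existence from the entrance region to the target.

    Source nodes each frame are the waters within ``source_radius`` of the
    entrance selection. For broken frames the breakpoint is charged to the
    relay residue nearest the largest gap: the closest approach between the
    source-connected and target-connected components of the H-bond graph.
    """
    labels = _relay_labels(traj.topology, relay_sel)
    # target atoms are graph nodes too, so a wire can terminate on them
    node_sel = Selection(
        expression=f"({relay_sel.expression}) or ({target_sel.expression})",
        indices=np.union1d(relay_sel.indices, target_sel.indices),
        label="relay+target",
    )
    exists, frames = [], []
    lengths: Counter = Counter()
    breaks: Counter = Counter()
    for i, coords, box in traj.iter_frames(stride):
        frames.append(i)
        graph = build_hbond_graph(coords, i, water_sel, node_sel,
                                  cutoff=cutoff, box=box)
        # source waters: within source_radius of the entrance selection
        if len(water_sel.indices):
            etree = geometry.periodic_tree(coords[entrance_sel.indices], box)
            wtree = geometry.periodic_tree(coords[water_sel.indices], box)
            hits = wtree.query_ball_tree(etree, r=source_radius * (1 + 1e-9))
            sources = water_sel.indices[np.array([len(h) > 0 for h in hits])]
        else:
            sources = np.array([], dtype=int)
        path = None
        if len(sources):
            path = find_wire(graph, sources, target_sel.indices)
        exists.append(path is not None)
        if path is not None:
            lengths[path.n_edges] += 1
        else:
            label = _attribute_break(graph, coords, box, sources,
                                     target_sel.indices, relay_sel, labels)
            if label is not None:
                breaks[label] += 1
    exists = np.array(exists, dtype=bool)
    return WireSummary(
        continuity_fraction=float(np.mean(exists)) if len(exists) else 0.0,
        exists=exists, path_lengths=lengths, breakpoint_counts=breaks,
        frames=np.array(frames), cutoff=cutoff,
    )


def _components(adj: dict[int, list[int]]) -> dict[int, int]:
    comp = {}
    cid = 0
    for start in sorted(adj):
        if start in comp:
            continue
        queue = deque([start])
        comp[start] = cid
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in comp:
                    comp[v] = cid
                    queue.append(v)
        cid += 1
    return comp


def _attribute_break(graph: HBondGraph, coords, box, sources, targets,
                     relay_sel: Selection, labels: dict[int, str]) -> str | None:
    """Relay residue nearest the largest gap between the source side and the
    target side of a broken wire."""
    if len(relay_sel.indices) == 0:
        return None
    adj = graph.adjacency()
    comp = _components(adj)
    src_comps = {comp[int(s)] for s in sources if int(s) in comp}
    tgt_comps = {comp[int(t)] for t in targets if int(t) in comp}
    src_nodes = [n for n, c in comp.items() if c in src_comps]
    tgt_nodes = [n for n, c in comp.items() if c in tgt_comps]
    if not src_nodes or not tgt_nodes:
        return None
    # closest approach between the two sides = the gap that breaks the wire
    best = None
    for u in src_nodes:
        d = geometry.min_image_distance(coords[u], coords[tgt_nodes], box)
        k = int(np.argmin(d))
        if best is None or d[k] < best[0]:
            best = (float(d[k]), u, tgt_nodes[k])
    _, u, v = best
    midpoint = coords[u] + geometry.min_image_displacement(
        coords[u], coords[v], box) / 2.0
    dr = geometry.min_image_distance(midpoint, coords[relay_sel.indices], box)
    nearest = int(relay_sel.indices[int(np.argmin(dr))])
    return labels[nearest]


def wire_frames_table(summary: WireSummary) -> pd.DataFrame:
    return pd.DataFrame({"frame": summary.frames,
                         "exists": summary.exists.astype(int)})
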