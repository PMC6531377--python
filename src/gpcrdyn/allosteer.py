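"""Allosteric communication pathways and pipelines on an MI-weighted graph.

Residues whose torsional motions are mutually informative and that are in
persistent spatial contact form a weighted graph.  The "shortest pathway
with maximum mutual information" between a source region (extracellular
surface) and a sink region (G-protein interface) is the minimum-cost path
under the transform

    cost(i, j) = -ln( MI_ij / MI_max )

which turns maximising the product of edge MIs into an additive
shortest-path problem with nonnegative costs.  Pathways that traverse the
orthosteric binding site are bundled into *pipelines*: connected components
of the pathway-overlap graph (two pathways overlap when they share at least
one edge).  A pipeline's strength is its member count; a residue's hub
count is the number of member pathways passing through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .traj_io import RegionSet, Topology, TrajectoryEnsemble
from .torsion_stats import MIMatrix

__all__ = [
    "ResidueGraph",
    "Pathway",
    "Pipeline",
    "build_graph",
    "proximity_pairs",
    "max_mi_path",
    "enumerate_pathways",
    "assemble_pipelines",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Pathway:
    residues: tuple[int, ...]        # ordered source -> sink
    total_mi: float
    total_cost: float
    passes_via: bool = False

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e)
                         for e in zip(self.residues[:-1], self.residues[1:]))

    @property
    def source(self) -> int:
        return self.residues[0]

    @property
    def sink(self) -> int:
        return self.residues[-1]


@dataclass
class Pipeline:
    members: list[Pathway]
    hub_counts: dict[int, int] = field(default_factory=dict)
    edge_counts: dict[frozenset, int] = field(default_factory=dict)

    @property
    def strength(self) -> int:
        return len(self.members)


class ResidueGraph:
    """MI-weighted residue graph restricted to spatially proximal pairs."""

    def __init__(self, graph: nx.Graph, mi_max: float):
        self.g = graph
        self.mi_max = mi_max

    @property
    def nodes(self) -> list[int]:
        return sorted(self.g.nodes)

    def edge_cost(self, i: int, j: int) -> float:
        return self.g[i][j]["cost"]


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def proximity_pairs(top: Topology, ens: TrajectoryEnsemble,
                    res_ids: list[int], cutoff: float = 5.0,
                    occupancy: float = 0.75) -> dict[frozenset, float]:
    """Residue pairs whose min heavy-atom distance is <= cutoff in >= the
    required fraction of analysis frames; values are the mean min distance."""
    coords = ens.analysis_coords()
    heavy = top.heavy_mask()
    idx = {r: top.atoms_of_residue(r)[heavy[top.atoms_of_residue(r)]]
           for r in res_ids}
    out: dict[frozenset, float] = {}
    for a_pos, i in enumerate(res_ids):
        for j in res_ids[a_pos + 1:]:
            xi = coords[:, idx[i], :]
            xj = coords[:, idx[j], :]
            d = np.linalg.norm(xi[:, :, None, :] - xj[:, None, :, :], axis=-1)
            dmin = d.min(axis=(1, 2))
            if float((dmin <= cutoff).mean()) >= occupancy:
                out[frozenset((i, j))] = float(dmin.mean())
    return out


def build_graph(top: Topology, ens: TrajectoryEnsemble, mi: MIMatrix,
                proximity_cutoff: float = 5.0,
                proximity_occupancy: float = 0.75,
                res_ids: list[int] | None = None) -> ResidueGraph:
    """Build the residue graph: edge (i, j) kept iff the pair is proximal
    (min heavy-atom distance <= cutoff in >= occupancy of analysis frames)
    and MI(i, j) > 0; edge cost = -ln(MI / MI_max)."""
    if res_ids is None:
        res_ids = sorted(mi.residues())
    prox = proximity_pairs(top, ens, res_ids, proximity_cutoff,
                           proximity_occupancy)
    return _graph_from_edges(
        {pair: (mi.pairs[pair], dist) for pair, dist in prox.items()
         if mi.pairs.get(pair, 0.0) > 0.0})


def _graph_from_edges(edges: dict[frozenset, tuple[float, float]]
                      ) -> ResidueGraph:
    """Assemble a ResidueGraph from {pair: (MI, mean_distance)}."""
    if not edges:
        raise ValueError("empty residue graph: no proximal pair has MI > 0 "
                         "(check the proximity cutoff/occupancy and the MI "
                         "matrix coverage)")
    mi_max = max(v[0] for v in edges.values())
    g = nx.Graph()
    for pair, (mi_val, dist) in edges.items():
        i, j = sorted(pair)
        g.add_edge(i, j, mi=mi_val, cost=float(-np.log(mi_val / mi_max)),
                   distance=dist)
    return ResidueGraph(g, mi_max)


# ---------------------------------------------------------------------------
# Path search
# ---------------------------------------------------------------------------

def max_mi_path(rg: ResidueGraph, source: int, sink: int) -> Pathway | None:
    """Minimum-cost (equivalently maximum product-of-MI) simple path.

    Dijkstra on the nonnegative edge costs; among equal-cost optima the
    lexicographically smallest residue sequence is returned, making the
    result deterministic.  Returns None when source and sink are
    disconnected.
    """
    g = rg.g
    if source not in g or sink not in g:
        raise KeyError(f"source {source} or sink {sink} not in graph")
    try:
        cands = list(nx.all_shortest_paths(g, source, sink, weight="cost"))
    except nx.NetworkXNoPath:
        return None
    path = min(cands)                      # lexicographic tie-break
    cost = sum(g[a][b]["cost"] for a, b in zip(path[:-1], path[1:]))
    mi = sum(g[a][b]["mi"] for a, b in zip(path[:-1], path[1:]))
    return Pathway(tuple(path), total_mi=float(mi), total_cost=float(cost))


def enumerate_pathways(rg: ResidueGraph, sources: RegionSet, sinks: RegionSet,
                       via: RegionSet | None = None) -> list[Pathway]:
    """Max-MI pathway for every (source, sink) pair, filtered by the via set.

    A pathway is retained only if at least one of its residues lies in
    ``via`` (the agonist binding site); pairs with no qualifying path are
    simply absent from the result.  With ``via=None`` all pairs' optimal
    paths are returned.
    """
    src = [r for r in sources.res_ids if r in rg.g]
    snk = [r for r in sinks.res_ids if r in rg.g]
    via_set = set(via.res_ids) if via is not None else None
    out = []
    for s in sorted(src):
        for t in sorted(snk):
            if s == t:
                continue
            p = max_mi_path(rg, s, t)
            if p is None:
                continue
            if via_set is not None:
                if not via_set.intersection(p.residues):
                    continue
                p.passes_via = True
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def assemble_pipelines(paths: list[Pathway],
                       overlap_min: int = 1) -> list[Pipeline]:
    """Bundle pathways into pipelines by edge overlap.

    Two pathways are adjacent when they share at least ``overlap_min``
    edges; pipelines are the connected components of this overlap graph.
    Strength = member count.  Pipelines are sorted by descending strength,
    ties broken by the smallest member residue id; members keep their
    enumeration order.
    """
    if not paths:
        raise ValueError("no pathways to assemble")
    og = nx.Graph()
    og.add_nodes_from(range(len(paths)))
    for a in range(len(paths)):
        for b in range(a + 1, len(paths)):
            if len(paths[a].edges & paths[b].edges) >= overlap_min:
                og.add_edge(a, b)
    pipelines = []
    for comp in nx.connected_components(og):
        members = [paths[k] for k in sorted(comp)]
        hubs: dict[int, int] = {}
        edge_counts: dict[frozenset, int] = {}
        for p in members:
            for r in set(p.residues):
                hubs[r] = hubs.get(r, 0) + 1
            for e in p.edges:
                edge_counts[e] = edge_counts.get(e, 0) + 1
        pipelines.append(Pipeline(members, hubs, edge_counts))
    pipelines.sort(key=lambda pl: (-pl.strength,
                                   min(min(p.residues) for p in pl.members)))
    return pipelines
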