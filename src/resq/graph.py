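"""Spatial residue graphs.

Nodes are residues (by residue index); edges come in three layers applied
in order: consecutive main-chain pairs, pairs closer than a distance
cutoff, and pairs sharing a neighbor (single closure pass). Edges are then
classified by the secondary-structure codes of their endpoints into five
classes: HH, BB, HB, CHB (coil with helix or strand) and CC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from resq.structure import SS_ALPHABET, StructureModel

EDGE_CLASSES = ("HH", "BB", "HB", "CHB", "CC")

#: edge origins, in the order layers are applied
ORIGINS = ("chain", "distance", "shared_neighbor", "fill")


@dataclass(frozen=True)
class Edge:
    distance: float  # Å (NaN for fill edges added during triangulation)
    origin: str
    edge_class: str | None = None


@dataclass
class ResidueGraph:
    """Undirected graph over residue indices.

    ``edges`` maps ordered pairs ``(i, j)`` with ``i < j`` to :class:`Edge`.
    ``node_order`` preserves the chain order of the residues, used to map
    secondary-structure strings onto nodes.
    """

    nodes: list[int]
    edges: dict[tuple[int, int], Edge]
    node_order: list[int]  # chain order (equals sorted nodes for valid models)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in self.nodes}
        for (a, b) in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def has_edge(self, i: int, j: int) -> bool:
        return _key(i, j) in self.edges


def _key(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ValueError("self-edge")
    return (i, j) if i < j else (j, i)


def build_graph(model: StructureModel, neighbor_cutoff: float) -> ResidueGraph:
    """Construct the three-layer residue graph at a neighbor cutoff.

    Layer 1 connects consecutive residues along the chain; layer 2 connects
    pairs with Cα distance strictly below ``neighbor_cutoff``; layer 3
    connects pairs that share a neighbor in the layer-1+2 graph (applied
    once, not iterated).
    """
    if neighbor_cutoff <= 0:
        raise ValueError(f"neighbor_cutoff must be positive, got {neighbor_cutoff}")

    idx = [int(v) for v in model.indices]
    coords = model.coords
    pos = {v: k for k, v in enumerate(idx)}
    edges: dict[tuple[int, int], Edge] = {}

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[pos[i]] - coords[pos[j]]))

    for a, b in zip(idx, idx[1:]):
        edges[_key(a, b)] = Edge(distance=dist(a, b), origin="chain")

    # pairwise distance layer (strict <)
    diffs = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diffs**2).sum(axis=-1))
    for p in range(len(idx)):
        for q in range(p + 1, len(idx)):
            if dmat[p, q] < neighbor_cutoff:
                key = _key(idx[p], idx[q])
                if key not in edges:
                    edges[key] = Edge(distance=float(dmat[p, q]), origin="distance")

    # shared-neighbor closure, single pass over the chain+distance edge set
    adj: dict[int, set[int]] = {v: set() for v in idx}
    for (a, b) in edges:
        adj[a].add(b)
        adj[b].add(a)
    for j in idx:
        nbrs = sorted(adj[j])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                key = _key(nbrs[x], nbrs[y])
                if key not in edges:
                    edges[key] = Edge(distance=dist(*key), origin="shared_neighbor")

    return ResidueGraph(nodes=sorted(idx), edges=edges, node_order=idx)


def classify_edges(graph: ResidueGraph, ss: str) -> ResidueGraph:
    """Fill in the secondary-structure class of every edge.

    The class depends only on the unordered pair of endpoint codes:
    H+H → HH, B+B → BB, H+B → HB, C with H or B → CHB, C+C → CC.
    """
    if len(ss) != len(graph.nodes):
        raise ValueError(f"ss length {len(ss)} != node count {len(graph.nodes)}")
    bad = set(ss) - SS_ALPHABET
    if bad:
        raise ValueError(f"unknown secondary structure codes: {sorted(bad)}")

    code = {node: ss[k] for k, node in enumerate(graph.node_order)}
    new_edges = {}
    for key, edge in graph.edges.items():
        a, b = code[key[0]], code[key[1]]
        new_edges[key] = replace(edge, edge_class=_pair_class(a, b))
    return ResidueGraph(nodes=list(graph.nodes), edges=new_edges, node_order=list(graph.node_order))


def _pair_class(a: str, b: str) -> str:
    pair = frozenset((a, b))
    if pair == {"H"}:
        return "HH"
    if pair == {"B"}:
        return "BB"
    if pair == {"H", "B"}:
        return "HB"
    if pair == {"C"}:
        return "CC"
    return "CHB"


def to_tsv(graph: ResidueGraph) -> str:
    """Edge list as TSV: node_i, node_j, distance, class, origin."""
    lines = ["node_i\tnode_j\tdistance\tclass\torigin"]
    for (a, b) in sorted(graph.edges):
        e = graph.edges[(a, b)]
        dist = "" if np.isnan(e.distance) else f"{e.distance:.4f}"
        lines.append(f"{a}\t{b}\t{dist}\t{e.edge_class or ''}\t{e.origin}")
    return "\n".join(lines) + "\n"


def from_tsv(text: str) -> ResidueGraph:
    """Inverse of :func:`to_tsv`; node order is ascending index."""
    edges: dict[tuple[int, int], Edge] = {}
    nodes: set[int] = set()
    lines = text.strip().splitlines()
    for line in lines[1:]:
        f = line.split("\t")
        a, b = int(f[0]), int(f[1])
        dist = float(f[2]) if f[2] else float("nan")
        edges[_key(a, b)] = Edge(distance=dist, origin=f[4], edge_class=f[3] or None)
        nodes.update((a, b))
    order = sorted(nodes)
    return ResidueGraph(nodes=order, edges=edges, node_order=order)
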