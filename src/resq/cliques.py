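"""Maximal cliques and clique (junction) trees.

A residue graph need not be chordal, so it is first triangulated with a
deterministic min-fill heuristic; the fill edges exist only to make exact
message passing valid and never carry model terms. Maximal cliques are
enumerated with Bron–Kerbosch (networkx) and linked into a maximum-weight
spanning tree over separator sizes, which for a chordal graph satisfies
the running intersection property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from resq.errors import InferenceError
from resq.graph import Edge, ResidueGraph, _key


@dataclass
class CliqueSet:
    """Maximal cliques of a graph, each a sorted tuple, listed lexicographically."""

    cliques: list[tuple[int, ...]]

    def __len__(self) -> int:
        return len(self.cliques)

    def __iter__(self):
        return iter(self.cliques)

    def __getitem__(self, i):
        return self.cliques[i]


@dataclass
class CliqueTree:
    """Spanning forest over maximal cliques with separator annotations.

    ``edges`` holds ``(a, b, separator)`` with ``a < b`` indexing into
    ``cliques``. Disconnected graphs give a forest (one tree per component).
    """

    cliques: list[tuple[int, ...]]
    edges: list[tuple[int, int, tuple[int, ...]]] = field(default_factory=list)

    def neighbors_of(self, ci: int) -> list[tuple[int, tuple[int, ...]]]:
        out = []
        for a, b, sep in self.edges:
            if a == ci:
                out.append((b, sep))
            elif b == ci:
                out.append((a, sep))
        return out


def triangulate(graph: ResidueGraph) -> tuple[ResidueGraph, list[tuple[int, int]]]:
    """Chordalize a graph with the min-fill heuristic (ties: lowest node index).

    Returns the chordal graph plus the list of fill edges added. Fill edges
    get origin="fill" and NaN distance; their class is inherited when
    edges are classified afterwards (or left None).
    """
    adj = graph.adjacency()
    remaining = set(graph.nodes)
    fills: list[tuple[int, int]] = []

    while remaining:
        # node whose neighborhood needs fewest fill edges
        best_v, best_cost = None, None
        for v in sorted(remaining):
            nbrs = [u for u in adj[v] if u in remaining]
            cost = 0
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    if nbrs[y] not in adj[nbrs[x]]:
                        cost += 1
            if best_cost is None or cost < best_cost:
                best_v, best_cost = v, cost
        v = best_v
        nbrs = sorted(u for u in adj[v] if u in remaining)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                a, b = nbrs[x], nbrs[y]
                if b not in adj[a]:
                    adj[a].add(b)
                    adj[b].add(a)
                    fills.append(_key(a, b))
        remaining.remove(v)

    if not fills:
        return graph, []
    new_edges = dict(graph.edges)
    for key in fills:
        new_edges[key] = Edge(distance=float("nan"), origin="fill")
    out = ResidueGraph(nodes=list(graph.nodes), edges=new_edges, node_order=list(graph.node_order))
    return out, fills


def enumerate_maximal_cliques(graph: ResidueGraph) -> CliqueSet:
    """All maximal cliques (Bron–Kerbosch with pivoting), deterministically ordered."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    cliques = sorted(tuple(sorted(c)) for c in nx.find_cliques(g))
    return CliqueSet(cliques=cliques)


def build_clique_tree(cliques: CliqueSet) -> CliqueTree:
    """Maximum-weight spanning forest of the clique graph (weight = |separator|).

    Ties are broken toward the lexicographically smaller clique pair.
    Running intersection is verified; a violation means the input cliques
    did not come from a chordal graph.
    """
    cls = list(cliques)
    n = len(cls)
    sets = [frozenset(c) for c in cls]

    candidates = []
    for a in range(n):
        for b in range(a + 1, n):
            sep = sets[a] & sets[b]
            if sep:
                candidates.append((-len(sep), cls[a], cls[b], a, b, tuple(sorted(sep))))
    candidates.sort()

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for _, _, _, a, b, sep in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, sep))

    tree = CliqueTree(cliques=cls, edges=sorted(edges))
    _verify_running_intersection(tree)
    return tree


def _verify_running_intersection(tree: CliqueTree) -> None:
    """For every node, cliques containing it must form a connected subtree."""
    containing: dict[int, list[int]] = {}
    for ci, clique in enumerate(tree.cliques):
        for v in clique:
            containing.setdefault(v, []).append(ci)
    for v, members in containing.items():
        if len(members) == 1:
            continue
        member_set = set(members)
        links = sum(1 for a, b, sep in tree.edges if v in sep and a in member_set and b in member_set)
        # a connected subtree over k cliques needs exactly k-1 linking edges
        if links != len(members) - 1:
            raise InferenceError(
                f"running intersection violated for node {v}: "
                f"{len(members)} cliques, {links} linking separators"
            )


def clique_tree_from_graph(graph: ResidueGraph) -> tuple[ResidueGraph, CliqueSet, CliqueTree]:
    """Triangulate, enumerate maximal cliques, and build the clique tree."""
    tri, _ = triangulate(graph)
    cset = enumerate_maximal_cliques(tri)
    return tri, cset, build_clique_tree(cset)


def cliques_to_tsv(cliques: CliqueSet) -> str:
    """TSV dump: clique id → comma-separated member residues."""
    lines = ["clique_id\tmembers"]
    for i, c in enumerate(cliques):
        lines.append(f"{i}\t{','.join(map(str, c))}")
    return "\n".join(lines) + "\n"
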