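"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from resq import crf
from resq.graph import Edge, ResidueGraph
from resq.structure import Residue, StructureModel


# ---------------------------------------------------------------------------
# builders


def make_graph(edges, classes=None, nodes=None):
    """ResidueGraph from an edge list (pairs), all origin='chain' unless classed."""
    edge_map = {}
    node_set = set(nodes or [])
    for k, (a, b) in enumerate(edges):
        key = (min(a, b), max(a, b))
        cls = None if classes is None else classes[k]
        edge_map[key] = Edge(distance=1.0, origin="chain", edge_class=cls)
        node_set.update(key)
    order = sorted(node_set)
    return ResidueGraph(nodes=order, edges=edge_map, node_order=order)


def chain_structure(coords, start_index=1):
    """StructureModel from raw coordinates, residues numbered consecutively."""
    coords = np.asarray(coords, dtype=float)
    residues = [
        Residue(index=start_index + i, name="ALA", ca=coords[i]) for i in range(len(coords))
    ]
    return StructureModel(residues=residues, model_id="test", chain_id="A")


def ideal_helix(n, rise=1.5, turn_deg=100.0, radius=2.3):
    t = np.arange(n)
    ang = np.radians(turn_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def random_instance(rng, n, m=3, extra_edge_p=0.25, with_labels=False):
    """Chain graph over n residues plus random extra edges, random features."""
    edges = [(i, i + 1) for i in range(1, n)]
    for a in range(1, n + 1):
        for b in range(a + 2, n + 1):
            if rng.random() < extra_edge_p:
                edges.append((a, b))
    classes = [
        ["HH", "BB", "HB", "CHB", "CC"][rng.integers(0, 5)] for _ in edges
    ]
    graph = make_graph(edges, classes=classes)
    features = rng.normal(size=(n, m))
    labels = rng.integers(0, 2, size=n) if with_labels else None
    return crf.build_instance(graph, features, labels=labels)


def random_params(rng, m, scale=1.0):
    lam = np.zeros((2, m))
    lam[1] = scale * rng.normal(size=m)
    omega = scale * rng.normal(size=4)
    return crf.CRFParameters(lam=lam, omega=omega)


# ---------------------------------------------------------------------------
# independent oracles


def horn_superpose(moving, fixed):
    """Closed-form quaternion (Horn) superposition, independent of the SVD route.

    Returns per-point distances after the optimal rigid alignment of
    ``moving`` onto ``fixed``.
    """
    p = np.asarray(moving, dtype=float)
    q = np.asarray(fixed, dtype=float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    s = pc.T @ qc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = pc @ rot.T + q.mean(axis=0)
    return np.linalg.norm(moved - q, axis=1)


def brute_force_maximal_cliques(graph: ResidueGraph):
    """All maximal cliques by 2^n subset enumeration (n <= 12)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    assert n <= 12
    adj = graph.adjacency()

    def is_clique(subset):
        return all(b in adj[a] for i, a in enumerate(subset) for b in subset[i + 1 :])

    cliques = []
    for mask in range(1, 2**n):
        subset = [nodes[i] for i in range(n) if mask & (1 << i)]
        if is_clique(subset):
            cliques.append(frozenset(subset))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return sorted(tuple(sorted(c)) for c in maximal)


def mcs_is_chordal(graph: ResidueGraph) -> bool:
    """Maximum cardinality search + perfect elimination ordering verification."""
    nodes = set(graph.nodes)
    adj = graph.adjacency()
    weight = {v: 0 for v in nodes}
    order = []
    unvisited = set(nodes)
    while unvisited:
        v = max(sorted(unvisited), key=lambda u: weight[u])
        order.append(v)
        unvisited.discard(v)
        for u in adj[v]:
            if u in unvisited:
                weight[u] += 1
    order.reverse()  # elimination order
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        later = [u for u in adj[v] if pos[u] > pos[v]]
        if not later:
            continue
        pivot = min(later, key=lambda u: pos[u])
        for u in later:
            if u != pivot and u not in adj[pivot]:
                return False
    return True


def brute_map_with_tie_rule(instance, params):
    """Argmax of the enumerated distribution, ties broken toward 1 earliest."""
    labelings, probs = crf.brute_force_distribution(instance, params)
    best = probs.max()
    candidates = [tuple(y) for y, p in zip(labelings, probs) if p >= best - 1e-15]
    # prefer label 1 at the earliest position: lexicographically largest vector
    return np.array(max(candidates), dtype=int)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
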