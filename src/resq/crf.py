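"""Conditional random field over a residue clique tree.

The label of every residue is binary: 1 = modelled position within the
error cutoff ("good"), 0 = above the cutoff. The unnormalized log-score of
a full labeling y given features x is

    E(y) = sum_r  lam[y_r, :] . x_r                      (node terms)
         + sum_(i,j) w[class(i,j)] * omega[pattern(y_i, y_j)]   (edge terms)

with lam[0, :] fixed at zero (reference label), omega indexed by the four
ordered label-pair patterns 00, 01, 10, 11 (lower residue index first),
and w a per-secondary-structure-class edge weight (all 1.0 by default).
Fill edges introduced by triangulation carry no edge term.

Each residue and each scored edge is assigned to exactly one "owner"
maximal clique, so that summing clique potentials reproduces E(y) without
double counting. Exact inference (sum-product marginals, max-product MAP)
runs on the clique tree; training maximizes the conditional log-likelihood
by stochastic gradient descent with expectations from calibrated clique
beliefs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from resq.cliques import CliqueSet, CliqueTree, build_clique_tree, enumerate_maximal_cliques, triangulate
from resq.errors import InferenceError
from resq.graph import EDGE_CLASSES, ResidueGraph

PAIR_PATTERNS = ("00", "01", "10", "11")

_NEG = -1.0e30  # log-space "impossible" sentinel (avoids -inf arithmetic warnings)


def pattern_index(y_low: int, y_high: int) -> int:
    """Index into omega for the ordered pair (label of lower residue, label of higher)."""
    return 2 * y_low + y_high


@dataclass
class CRFParameters:
    """Weights of the model plus the settings they were trained for."""

    lam: np.ndarray  # (2, m); row 0 is the fixed zero reference
    omega: np.ndarray  # (4,) indexed by PAIR_PATTERNS
    edge_weights: dict[str, float] = field(default_factory=lambda: {c: 1.0 for c in EDGE_CLASSES})
    ca_cutoff: float = 5.0
    neighbor_cutoff: float = 4.5
    feature_names: list[str] | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.lam.ndim != 2 or self.lam.shape[0] != 2:
            raise ValueError("lam must have shape (2, m)")
        if self.omega.shape != (4,):
            raise ValueError("omega must have length 4")
        for c, w in self.edge_weights.items():
            if c not in EDGE_CLASSES:
                raise ValueError(f"unknown edge class {c!r}")
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"edge weight for {c} must be in [0, 1], got {w}")

    @property
    def n_features(self) -> int:
        return self.lam.shape[1]

    @classmethod
    def zeros(cls, n_features: int, **kw) -> "CRFParameters":
        return cls(lam=np.zeros((2, n_features)), omega=np.zeros(4), **kw)

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "lam": [[float(v) for v in row] for row in self.lam],
            "omega": [float(v) for v in self.omega],
            "edge_weights": {c: float(self.edge_weights.get(c, 1.0)) for c in EDGE_CLASSES},
            "ca_cutoff": self.ca_cutoff,
            "neighbor_cutoff": self.neighbor_cutoff,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CRFParameters":
        d = json.loads(text)
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported parameter schema version {d.get('schema_version')}")
        return cls(
            lam=np.array(d["lam"]),
            omega=np.array(d["omega"]),
            edge_weights=d["edge_weights"],
            ca_cutoff=d["ca_cutoff"],
            neighbor_cutoff=d["neighbor_cutoff"],
            feature_names=d["feature_names"],
            seed=d["seed"],
            metadata=d.get("metadata", {}),
        )


@dataclass
class GraphModelInstance:
    """A model ready for inference: graph + clique tree + features (+labels).

    ``features`` rows follow ascending residue index (``nodes``). Ownership
    maps assign each residue and each scored (non-fill) edge to exactly one
    maximal clique of the triangulated graph.
    """

    graph: ResidueGraph  # original (pre-triangulation) graph, classes filled or not
    tri_graph: ResidueGraph
    cliques: CliqueSet
    tree: CliqueTree
    features: np.ndarray  # (n, m)
    nodes: list[int]  # ascending residue indices; row order of features
    node_pos: dict[int, int]
    owner_node: dict[int, int]  # residue index -> clique id
    owner_edge: dict[tuple[int, int], int]  # scored edge -> clique id
    labels: np.ndarray | None = None  # (n,) ints, optional ground truth
    model_id: str = "instance"

    @property
    def n_residues(self) -> int:
        return len(self.nodes)

    @property
    def scored_edges(self) -> list[tuple[int, int]]:
        return sorted(self.owner_edge)


def build_instance(
    graph: ResidueGraph,
    features: np.ndarray,
    labels: np.ndarray | None = None,
    model_id: str = "instance",
) -> GraphModelInstance:
    """Triangulate, build the clique tree, and assign owners.

    Owner of a residue (edge): the smallest clique containing it, ties
    broken by lexicographic clique member tuple.
    """
    features = np.asarray(features, dtype=float)
    nodes = sorted(graph.nodes)
    if features.shape[0] != len(nodes):
        raise ValueError(f"features rows ({features.shape[0]}) != node count ({len(nodes)})")
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (len(nodes),):
            raise ValueError("labels length must equal node count")

    tri, _ = triangulate(graph)
    cset = enumerate_maximal_cliques(tri)
    tree = build_clique_tree(cset)

    by_size = sorted(range(len(cset)), key=lambda ci: (len(cset[ci]), cset[ci]))
    owner_node: dict[int, int] = {}
    for ci in by_size:
        for v in cset[ci]:
            owner_node.setdefault(v, ci)

    owner_edge: dict[tuple[int, int], int] = {}
    for key, edge in graph.edges.items():
        if edge.origin == "fill":
            continue
        a, b = key
        for ci in by_size:
            members = set(cset[ci])
            if a in members and b in members:
                owner_edge[key] = ci
                break
        else:  # pragma: no cover - triangulation guarantees a containing clique
            raise InferenceError(f"edge {key} not inside any maximal clique")

    return GraphModelInstance(
        graph=graph,
        tri_graph=tri,
        cliques=cset,
        tree=tree,
        features=features,
        nodes=nodes,
        node_pos={v: k for k, v in enumerate(nodes)},
        owner_node=owner_node,
        owner_edge=owner_edge,
        labels=labels,
        model_id=model_id,
    )


# ---------------------------------------------------------------------------
# potentials


def _edge_weight(params: CRFParameters, edge_class: str | None) -> float:
    if edge_class is None:
        return 1.0
    return params.edge_weights.get(edge_class, 1.0)


def _node_gain(instance: GraphModelInstance, params: CRFParameters) -> np.ndarray:
    """Per-residue log-score difference of label 1 over label 0: (lam1 - lam0) . x."""
    diff = params.lam[1] - params.lam[0]
    return instance.features @ diff


def clique_log_potential(
    instance: GraphModelInstance,
    params: CRFParameters,
    clique_id: int,
    labels_on_clique: Sequence[int],
) -> float:
    """Log-potential of one clique for a full labeling of its members.

    Sums node terms of residues owned by the clique and edge terms of edges
    owned by it; together the clique potentials add up to the global E(y).
    """
    clique = instance.cliques[clique_id]
    if len(labels_on_clique) != len(clique):
        raise ValueError("labels_on_clique must label every clique member")
    label_of = dict(zip(clique, labels_on_clique))

    total = 0.0
    for v, y in label_of.items():
        if instance.owner_node.get(v) == clique_id:
            total += float(params.lam[y] @ instance.features[instance.node_pos[v]])
    for (a, b), owner in instance.owner_edge.items():
        if owner == clique_id:
            w = _edge_weight(params, instance.graph.edges[(a, b)].edge_class)
            total += w * float(params.omega[pattern_index(label_of[a], label_of[b])])
    return total


def enumerate_clique_labelings(
    instance: GraphModelInstance, params: CRFParameters, clique_id: int
) -> list[tuple[tuple[int, ...], float]]:
    """Exhaustive factor evaluation: every joint labeling of a clique with its log-potential."""
    k = len(instance.cliques[clique_id])
    out = []
    for bits in range(2**k):
        labels = tuple((bits >> (k - 1 - t)) & 1 for t in range(k))
        out.append((labels, clique_log_potential(instance, params, clique_id, labels)))
    return out


def _clique_factors(instance: GraphModelInstance, params: CRFParameters) -> list[np.ndarray]:
    """Log-factor arrays, one per clique, shape (2,)*len(clique)."""
    gain = _node_gain(instance, params)
    base = instance.features @ params.lam[0]  # label-0 node score (zero when lam0 == 0)
    factors = []
    for ci, clique in enumerate(instance.cliques):
        k = len(clique)
        f = np.zeros((2,) * k)
        for axis, v in enumerate(clique):
            if instance.owner_node.get(v) == ci:
                shape = [1] * k
                shape[axis] = 2
                row = instance.node_pos[v]
                f = f + np.array([base[row], base[row] + gain[row]]).reshape(shape)
        for (a, b), owner in instance.owner_edge.items():
            if owner != ci:
                continue
            w = _edge_weight(params, instance.graph.edges[(a, b)].edge_class)
            pa, pb = clique.index(a), clique.index(b)
            table = w * params.omega.reshape(2, 2)  # [y_a, y_b]
            shape = [1] * k
            shape[pa] = 2
            shape[pb] = 2
            if pa < pb:
                f = f + table.reshape(shape)
            else:
                f = f + table.T.reshape(shape)
        factors.append(f)
    return factors


def _apply_clamp(
    instance: GraphModelInstance, factors: list[np.ndarray], clamp: dict[int, int]
) -> list[np.ndarray]:
    out = []
    for ci, clique in enumerate(instance.cliques):
        f = factors[ci]
        touched = False
        for axis, v in enumerate(clique):
            if v in clamp:
                if not touched:
                    f = f.copy()
                    touched = True
                sl = [slice(None)] * f.ndim
                sl[axis] = 1 - clamp[v]
                f[tuple(sl)] = _NEG
        out.append(f)
    return out


# ---------------------------------------------------------------------------
# message passing


def _marginalize(arr: np.ndarray, keep_axes: tuple[int, ...], mode: str) -> np.ndarray:
    drop = tuple(ax for ax in range(arr.ndim) if ax not in keep_axes)
    if not drop:
        return arr
    if mode == "sum":
        return logsumexp(arr, axis=drop)
    return arr.max(axis=drop)


def _expand(msg: np.ndarray, sep: tuple[int, ...], clique: tuple[int, ...]) -> np.ndarray:
    """Broadcast a separator message onto a clique's axes (both sorted)."""
    shape = [2 if v in sep else 1 for v in clique]
    return msg.reshape(shape)


def _rooted_orders(tree: CliqueTree) -> list[list[tuple[int, int, tuple[int, ...]]]]:
    """Per-component lists of (child, parent, separator) in leaves-first order."""
    n = len(tree.cliques)
    adj: dict[int, list[tuple[int, tuple[int, ...]]]] = {i: [] for i in range(n)}
    for a, b, sep in tree.edges:
        adj[a].append((b, sep))
        adj[b].append((a, sep))
    seen = [False] * n
    components = []
    for root in range(n):
        if seen[root]:
            continue
        order = []
        stack = [(root, -1, ())]
        seen[root] = True
        visit = []
        while stack:
            node, parent, sep = stack.pop()
            visit.append((node, parent, sep))
            for nb, s in adj[node]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append((nb, node, s))
        # child->parent order: reverse of DFS pre-order
        for node, parent, sep in reversed(visit):
            if parent >= 0:
                order.append((node, parent, sep))
        components.append(order)
    return components


def _calibrate(
    instance: GraphModelInstance, factors: list[np.ndarray], mode: str
) -> tuple[list[np.ndarray], float]:
    """Two-pass message passing; returns clique beliefs (log) and log Z.

    In "max" mode the returned scalar is the maximal log-score instead of
    log Z.
    """
    cliques = instance.cliques
    n = len(cliques)
    msgs: dict[tuple[int, int], np.ndarray] = {}  # (src, dst) -> message over separator
    components = _rooted_orders(instance.tree)

    incoming: dict[int, list[tuple[int, tuple[int, ...]]]] = {i: [] for i in range(n)}
    for a, b, sep in instance.tree.edges:
        incoming[a].append((b, sep))
        incoming[b].append((a, sep))

    def message(src: int, dst: int, sep: tuple[int, ...]) -> np.ndarray:
        work = factors[src]
        for nb, s in incoming[src]:
            if nb != dst and (nb, src) in msgs:
                work = work + _expand(msgs[(nb, src)], s, cliques[src])
        keep = tuple(ax for ax, v in enumerate(cliques[src]) if v in sep)
        return _marginalize(work, keep, mode)

    # upward (leaves -> root)
    for order in components:
        for child, parent, sep in order:
            msgs[(child, parent)] = message(child, parent, sep)
    # downward (root -> leaves)
    for order in components:
        for child, parent, sep in reversed(order):
            msgs[(parent, child)] = message(parent, child, sep)

    beliefs = []
    for ci in range(n):
        b = factors[ci]
        for nb, sep in incoming[ci]:
            b = b + _expand(msgs[(nb, ci)], sep, cliques[ci])
        beliefs.append(b)

    # one scalar per component, read off its root clique
    total = 0.0
    roots = set(range(n))
    for order in components:
        for child, parent, sep in order:
            roots.discard(child)
    for r in sorted(roots):
        if mode == "sum":
            total += float(logsumexp(beliefs[r]))
        else:
            total += float(beliefs[r].max())
    return beliefs, total


# ---------------------------------------------------------------------------
# inference


def energy(instance: GraphModelInstance, params: CRFParameters, labels: np.ndarray) -> float:
    """Global log-score E(y): direct sum over node and scored-edge terms."""
    labels = np.asarray(labels, dtype=int)
    gain = _node_gain(instance, params)
    base = instance.features @ params.lam[0]
    total = float(base.sum() + gain[labels == 1].sum())
    for (a, b) in instance.owner_edge:
        w = _edge_weight(params, instance.graph.edges[(a, b)].edge_class)
        ya = labels[instance.node_pos[a]]
        yb = labels[instance.node_pos[b]]
        total += w * float(params.omega[pattern_index(ya, yb)])
    return total


def log_partition(instance: GraphModelInstance, params: CRFParameters) -> float:
    factors = _clique_factors(instance, params)
    _, logz = _calibrate(instance, factors, "sum")
    return logz


def log_likelihood(instance: GraphModelInstance, params: CRFParameters) -> float:
    if instance.labels is None:
        raise ValueError("instance has no labels")
    return energy(instance, params, instance.labels) - log_partition(instance, params)


def brute_force_distribution(
    instance: GraphModelInstance, params: CRFParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution by 2^N enumeration (N <= 16).

    Returns (labelings, probabilities); labelings[k] is the binary vector
    whose bits, read in ascending residue order, encode the integer k
    (residue 0 = most significant bit).
    """
    n = instance.n_residues
    if n > 16:
        raise ValueError(f"{n} residues is too large for enumeration; use infer_marginals")
    codes = np.arange(2**n)[:, None]
    shifts = np.arange(n - 1, -1, -1)[None, :]
    labelings = ((codes >> shifts) & 1).astype(int)

    gain = _node_gain(instance, params)
    base = float((instance.features @ params.lam[0]).sum())
    scores = base + labelings @ gain
    for (a, b) in instance.owner_edge:
        w = _edge_weight(params, instance.graph.edges[(a, b)].edge_class)
        pat = 2 * labelings[:, instance.node_pos[a]] + labelings[:, instance.node_pos[b]]
        scores = scores + w * params.omega[pat]
    logz = logsumexp(scores)
    return labelings, np.exp(scores - logz)


def infer_marginals(instance: GraphModelInstance, params: CRFParameters) -> np.ndarray:
    """Exact per-residue P(y=1) from calibrated sum-product beliefs."""
    factors = _clique_factors(instance, params)
    beliefs, _ = _calibrate(instance, factors, "sum")
    p1 = np.empty(instance.n_residues)
    for v in instance.nodes:
        ci = instance.owner_node[v]
        clique = instance.cliques[ci]
        axis = clique.index(v)
        marg = _marginalize(beliefs[ci], (axis,), "sum")
        marg = marg - logsumexp(marg)
        p1[instance.node_pos[v]] = math.exp(marg[1])
    return p1


def pairwise_marginals(
    instance: GraphModelInstance, params: CRFParameters
) -> dict[tuple[int, int], np.ndarray]:
    """P(pattern) over the 4 ordered patterns for every scored edge."""
    factors = _clique_factors(instance, params)
    beliefs, _ = _calibrate(instance, factors, "sum")
    out = {}
    for (a, b), ci in instance.owner_edge.items():
        clique = instance.cliques[ci]
        pa, pb = clique.index(a), clique.index(b)
        marg = _marginalize(beliefs[ci], tuple(sorted((pa, pb))), "sum")
        if pa > pb:
            marg = marg.T
        marg = marg - logsumexp(marg)
        out[(a, b)] = np.exp(marg).reshape(4)  # index = 2*y_a + y_b
    return out


def _max_score(instance: GraphModelInstance, factors: list[np.ndarray], clamp: dict[int, int]) -> float:
    clamped = _apply_clamp(instance, factors, clamp)
    _, best = _calibrate(instance, clamped, "max")
    return best


def infer_map(instance: GraphModelInstance, params: CRFParameters) -> np.ndarray:
    """Exact MAP labeling by max-product with tie-safe decoding.

    Fast path: when every residue's max-marginal has a strict argmax the
    (unique) maximizer is read off one calibration. Otherwise ties are
    resolved sequentially toward label 1 at the lowest-index undecided
    residue, selecting the maximizer that prefers 1 earliest.
    """
    factors = _clique_factors(instance, params)
    beliefs, _ = _calibrate(instance, factors, "max")
    labels = np.empty(instance.n_residues, dtype=int)
    tied = False
    for v in instance.nodes:
        ci = instance.owner_node[v]
        axis = instance.cliques[ci].index(v)
        mm = _marginalize(beliefs[ci], (axis,), "max")
        if abs(mm[1] - mm[0]) < 1e-9:
            tied = True
            break
        labels[instance.node_pos[v]] = int(mm[1] > mm[0])
    if not tied:
        return labels

    clamp: dict[int, int] = {}
    for v in instance.nodes:
        clamp[v] = 1
        s1 = _max_score(instance, factors, clamp)
        clamp[v] = 0
        s0 = _max_score(instance, factors, clamp)
        clamp[v] = 1 if s1 >= s0 else 0
    return np.array([clamp[v] for v in instance.nodes], dtype=int)


@dataclass
class QualityPrediction:
    """Per-residue MAP label, marginal P(good), and the model-level good fraction."""

    map_labels: np.ndarray
    marginal_p1: np.ndarray
    fraction_good: float
    residue_indices: list[int]


def predict(instance: GraphModelInstance, params: CRFParameters) -> QualityPrediction:
    marg = infer_marginals(instance, params)
    labels = infer_map(instance, params)
    return QualityPrediction(
        map_labels=labels,
        marginal_p1=marg,
        fraction_good=float(labels.mean()),
        residue_indices=list(instance.nodes),
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class SGDHyper:
    learning_rate: float = 0.05
    epochs: int = 50
    l2_penalty: float = 1e-3
    seed: int = 0
    decay: bool = True  # 1/sqrt(epoch) learning-rate decay


def _instance_statistics(
    instance: GraphModelInstance, params: CRFParameters
) -> tuple[np.ndarray, np.ndarray]:
    """(observed - expected) sufficient statistics for (lam1, omega)."""
    if instance.labels is None:
        raise ValueError(f"instance {instance.model_id} has no labels")
    y = instance.labels
    x = instance.features

    factors = _clique_factors(instance, params)
    beliefs, _ = _calibrate(instance, factors, "sum")

    p1 = np.empty(instance.n_residues)
    for v in instance.nodes:
        ci = instance.owner_node[v]
        axis = instance.cliques[ci].index(v)
        marg = _marginalize(beliefs[ci], (axis,), "sum")
        p1[instance.node_pos[v]] = math.exp(marg[1] - logsumexp(marg))
    grad_lam1 = ((y == 1).astype(float) - p1) @ x

    grad_omega = np.zeros(4)
    for (a, b), ci in instance.owner_edge.items():
        clique = instance.cliques[ci]
        pa, pb = clique.index(a), clique.index(b)
        marg = _marginalize(beliefs[ci], tuple(sorted((pa, pb))), "sum")
        if pa > pb:
            marg = marg.T
        probs = np.exp(marg - logsumexp(marg)).reshape(4)
        w = _edge_weight(params, instance.graph.edges[(a, b)].edge_class)
        ya, yb = y[instance.node_pos[a]], y[instance.node_pos[b]]
        grad_omega[pattern_index(ya, yb)] += w
        grad_omega -= w * probs
    return grad_lam1, grad_omega


def train_sgd(
    dataset: Sequence[GraphModelInstance],
    hyper: SGDHyper | None = None,
    edge_weights: dict[str, float] | None = None,
    ca_cutoff: float = 5.0,
    neighbor_cutoff: float = 4.5,
    feature_names: list[str] | None = None,
) -> tuple[CRFParameters, list[float]]:
    """Maximize the L2-penalized conditional log-likelihood by SGD.

    One gradient step per model instance; instance order reshuffled every
    epoch from the stated seed; parameters start at zero. Returns the
    trained parameters and the per-epoch total training log-likelihood.
    """
    if hyper is None:
        hyper = SGDHyper()
    if not dataset:
        raise ValueError("empty training dataset")
    m = dataset[0].features.shape[1]
    ew = dict(edge_weights) if edge_weights else {c: 1.0 for c in EDGE_CLASSES}
    params = CRFParameters.zeros(
        m,
        edge_weights=ew,
        ca_cutoff=ca_cutoff,
        neighbor_cutoff=neighbor_cutoff,
        feature_names=feature_names,
        seed=hyper.seed,
        metadata={
            "learning_rate": hyper.learning_rate,
            "epochs": hyper.epochs,
            "l2_penalty": hyper.l2_penalty,
        },
    )
    rng = np.random.default_rng(hyper.seed)
    order = np.arange(len(dataset))
    trace: list[float] = []
    for epoch in range(hyper.epochs):
        lr = hyper.learning_rate / math.sqrt(epoch + 1) if hyper.decay else hyper.learning_rate
        rng.shuffle(order)
        for k in order:
            inst = dataset[k]
            g_lam1, g_omega = _instance_statistics(inst, params)
            if not (np.all(np.isfinite(g_lam1)) and np.all(np.isfinite(g_omega))):
                raise InferenceError(f"non-finite gradient on instance {inst.model_id}")
            params.lam[1] += lr * (g_lam1 - hyper.l2_penalty * params.lam[1])
            params.omega += lr * (g_omega - hyper.l2_penalty * params.omega)
        trace.append(sum(log_likelihood(inst, params) for inst in dataset))
    return params, trace


# ---------------------------------------------------------------------------
# baselines


def fit_logistic_regression(
    features: np.ndarray, labels: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Maximum-likelihood logistic regression; returns (m+1,) = [intercept, coefs].

    Newton/IRLS-style ascent via scipy's BFGS on the exact gradient;
    perfect separation is caught by the iteration cap with a warning.
    """
    from scipy.optimize import minimize

    x = np.column_stack([np.ones(len(features)), np.asarray(features, dtype=float)])
    y = np.asarray(labels, dtype=float)

    def negll(beta: np.ndarray) -> tuple[float, np.ndarray]:
        z = x @ beta
        # log(1 + e^z) computed stably
        ll = float(y @ z - np.logaddexp(0.0, z).sum())
        p = 1.0 / (1.0 + np.exp(-z))
        return -ll, -(x.T @ (y - p))

    res = minimize(negll, np.zeros(x.shape[1]), jac=True, method="BFGS",
                   options={"gtol": tol, "maxiter": max_iter})
    if not res.success:
        import logging

        logging.getLogger(__name__).warning(
            "logistic fit did not fully converge (%s); possible perfect separation", res.message
        )
    return res.x


def logistic_predict(beta: np.ndarray, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, labels at threshold 0.5)."""
    x = np.column_stack([np.ones(len(features)), np.asarray(features, dtype=float)])
    p = 1.0 / (1.0 + np.exp(-(x @ beta)))
    return p, (p >= 0.5).astype(int)
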