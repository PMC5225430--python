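"""Synthetic structures and CRF-sampled datasets.

Everything here is a pure function of its seed: toy Cα traces with known
secondary-structure geometry, perturbed copies with planted per-region
errors, and feature/label datasets sampled from a CRF with known
parameters so that training can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from resq import crf
from resq.graph import EDGE_CLASSES, build_graph, classify_edges
from resq.structure import Residue, StructureModel

HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TURN = math.radians(100.0)  # per residue
HELIX_RADIUS = 2.3  # Å
STRAND_RISE = 3.5  # Å per residue along the strand axis
CA_SPACING = 3.8  # target consecutive Cα distance, Å

# zig-zag offset so that consecutive strand Cα distance is 3.8 Å
_STRAND_ZIGZAG = math.sqrt(CA_SPACING**2 - STRAND_RISE**2) / 2.0


@dataclass
class SyntheticSpec:
    """Recipe for a seeded synthetic dataset."""

    n_models: int = 20
    n_residues: int = 15
    ss_layout: str = "CCHHHHHCCBBBCCC"
    displacement: dict[str, float] = field(default_factory=dict)
    lam1: np.ndarray = field(default_factory=lambda: np.array([1.0, -1.0, 0.5, 0.0]))
    omega: np.ndarray = field(default_factory=lambda: np.array([0.4, -0.9, -0.9, 1.2]))
    neighbor_cutoff: float = 4.5
    feature_noise: float = 1.0
    seed: int = 0


def _rotation_to(z_axis: np.ndarray) -> np.ndarray:
    """A rotation matrix whose third column is the given unit vector."""
    z = z_axis / np.linalg.norm(z_axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = ref - z * (ref @ z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _segment_coords(code: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Local coordinates of an n-residue segment of one structure type."""
    if code == "H":
        t = np.arange(n)
        return np.column_stack([
            HELIX_RADIUS * np.cos(HELIX_TURN * t),
            HELIX_RADIUS * np.sin(HELIX_TURN * t),
            HELIX_RISE * t,
        ])
    if code == "B":
        t = np.arange(n)
        zig = _STRAND_ZIGZAG * np.where(t % 2 == 0, 1.0, -1.0)
        return np.column_stack([zig, np.zeros(n), STRAND_RISE * t])
    # coil: persistent random walk with ~3.8 Å steps
    coords = [np.zeros(3)]
    direction = _random_unit(rng)
    for _ in range(n - 1):
        direction = direction + 0.8 * _random_unit(rng)
        direction /= np.linalg.norm(direction)
        step = CA_SPACING + rng.uniform(-0.1, 0.1)
        coords.append(coords[-1] + step * direction)
    return np.array(coords)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_toy_structure(n_residues: int, ss_layout: str, seed: int = 0) -> StructureModel:
    """A Cα trace realizing an H/B/C layout with idealized local geometry.

    Helix runs use 1.5 Å rise / 100° per residue / 2.3 Å radius; strand
    runs a 3.5 Å-per-residue zig-zag; coil a jittered random walk.
    Consecutive Cα spacing stays within 3.8 ± 0.1 Å.
    """
    if len(ss_layout) != n_residues:
        raise ValueError(f"ss_layout length {len(ss_layout)} != n_residues {n_residues}")
    if set(ss_layout) - set("HBC"):
        raise ValueError(f"invalid ss_layout characters: {set(ss_layout) - set('HBC')}")

    rng = np.random.default_rng(seed)
    runs: list[tuple[str, int]] = []
    for c in ss_layout:
        if runs and runs[-1][0] == c:
            runs[-1] = (c, runs[-1][1] + 1)
        else:
            runs.append((c, 1))

    coords: list[np.ndarray] = []
    for code, length in runs:
        seg = _segment_coords(code, length, rng)
        if not coords:
            placed = seg
        else:
            # reorient the segment and continue 3.8 Å from the last residue
            rot = _rotation_to(_random_unit(rng))
            seg = seg @ rot.T
            step = seg[1] - seg[0] if length > 1 else rot[:, 2] * CA_SPACING
            step = step / np.linalg.norm(step) * CA_SPACING
            offset = coords[-1] + step - seg[0]
            placed = seg + offset
        coords.extend(placed)

    residues = [
        Residue(index=i + 1, name="ALA", ca=coords[i]) for i in range(n_residues)
    ]
    return StructureModel(residues=residues, model_id=f"toy-{seed}", chain_id="A")


def perturb_model(
    native: StructureModel, displacement_profile: np.ndarray, seed: int = 0
) -> StructureModel:
    """Displace Cα positions with per-residue magnitudes, correlated within regions.

    Contiguous runs of equal magnitude share a random direction; each
    residue adds isotropic noise scaled by its magnitude. A zero profile
    returns identical coordinates.
    """
    profile = np.asarray(displacement_profile, dtype=float)
    if profile.shape != (len(native),):
        raise ValueError("displacement profile must assign a magnitude to each residue")
    if np.any(profile < 0):
        raise ValueError("displacement magnitudes must be >= 0")

    rng = np.random.default_rng(seed)
    coords = native.coords.copy()
    start = 0
    while start < len(native):
        end = start
        while end + 1 < len(native) and profile[end + 1] == profile[start]:
            end += 1
        mag = profile[start]
        if mag > 0:
            shared = _random_unit(rng)
            for i in range(start, end + 1):
                noise = 0.3 * rng.normal(size=3)
                coords[i] = coords[i] + mag * (shared + noise)
        start = end + 1

    residues = [
        Residue(index=r.index, name=r.name, ca=coords[i])
        for i, r in enumerate(native.residues)
    ]
    return StructureModel(residues=residues, model_id=f"{native.model_id}-perturbed", chain_id=native.chain_id)


# ---------------------------------------------------------------------------
# CRF-sampled datasets


def _planted_params(spec: SyntheticSpec) -> crf.CRFParameters:
    lam = np.zeros((2, len(spec.lam1)))
    lam[1] = np.asarray(spec.lam1, dtype=float)
    return crf.CRFParameters(
        lam=lam,
        omega=np.asarray(spec.omega, dtype=float),
        edge_weights={c: 1.0 for c in EDGE_CLASSES},
        neighbor_cutoff=spec.neighbor_cutoff,
        seed=spec.seed,
    )


def _sample_labels_exact(
    instance: crf.GraphModelInstance,
    params: crf.CRFParameters,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Exact draw(s) from the planted conditional label distribution."""
    labelings, probs = crf.brute_force_distribution(instance, params)
    k = rng.choice(len(probs), p=probs, size=size)
    return labelings[k].copy()


def _sample_labels_gibbs(
    instance: crf.GraphModelInstance,
    params: crf.CRFParameters,
    rng: np.random.Generator,
    burn_in: int = 1000,
) -> np.ndarray:
    n = instance.n_residues
    y = rng.integers(0, 2, size=n)
    gain = instance.features @ (params.lam[1] - params.lam[0])
    nbrs: dict[int, list[tuple[int, bool, float]]] = {v: [] for v in instance.nodes}
    for (a, b) in instance.owner_edge:
        w = params.edge_weights.get(instance.graph.edges[(a, b)].edge_class or "", 1.0)
        nbrs[a].append((instance.node_pos[b], True, w))  # a is the lower index
        nbrs[b].append((instance.node_pos[a], False, w))
    for sweep in range(burn_in + 1):
        for v in instance.nodes:
            pos = instance.node_pos[v]
            s = np.zeros(2)
            s[1] += gain[pos]
            for other_pos, is_low, w in nbrs[v]:
                yo = y[other_pos]
                for lab in (0, 1):
                    pat = crf.pattern_index(lab, yo) if is_low else crf.pattern_index(yo, lab)
                    s[lab] += w * params.omega[pat]
            p1 = 1.0 / (1.0 + math.exp(s[0] - s[1]))
            y[pos] = int(rng.random() < p1)
    return y


def sample_benchmark(spec: SyntheticSpec):
    """Model records (structure + raw features + labels) with planted CRF labels.

    Like :func:`sample_crf_dataset` but keeps the generating structures so
    downstream pipelines can rebuild graphs at any neighbor cutoff (e.g.
    comparing the full model with the 1.0 Å linear degeneration). Returns
    ``(records, planted_params)``.
    """
    from resq.evaluate import ModelRecord

    structures, instances, params = _sample_models(spec)
    records = [
        ModelRecord(
            model_id=inst.model_id,
            structure=structure,
            features_raw=inst.features.copy(),
            labels=inst.labels.copy(),
            ss=spec.ss_layout,
        )
        for structure, inst in zip(structures, instances)
    ]
    return records, params


def sample_crf_dataset(spec: SyntheticSpec) -> tuple[list[crf.GraphModelInstance], crf.CRFParameters]:
    """Instances with Gaussian features and labels drawn from a planted CRF.

    Each model gets a fresh toy structure (same layout, different seed),
    i.i.d. N(0, feature_noise²) features, and labels sampled exactly from
    the planted conditional distribution (inverse CDF over the brute-force
    enumeration for <= 16 residues, Gibbs sampling beyond that). Returns
    the dataset together with the planted truth.
    """
    _, instances, params = _sample_models(spec)
    return instances, params


def _sample_models(spec: SyntheticSpec):
    params = _planted_params(spec)
    rng = np.random.default_rng(spec.seed)
    m = len(spec.lam1)
    structures = []
    instances = []
    for k in range(spec.n_models):
        structure = generate_toy_structure(
            spec.n_residues, spec.ss_layout, seed=int(rng.integers(0, 2**31))
        )
        graph = build_graph(structure, spec.neighbor_cutoff)
        graph = classify_edges(graph, spec.ss_layout)
        features = spec.feature_noise * rng.normal(size=(spec.n_residues, m))
        inst = crf.build_instance(graph, features, model_id=f"synth-{spec.seed}-{k}")
        if spec.n_residues <= 16:
            inst.labels = _sample_labels_exact(inst, params, rng)
        else:
            inst.labels = _sample_labels_gibbs(inst, params, rng)
        structures.append(structure)
        instances.append(inst)
    return structures, instances, params
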