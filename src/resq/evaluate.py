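"""Label generation, scoring metrics, cross-validation, and weight search.

True per-residue labels come from superposing a model onto its native
structure: label 1 ("good") iff the Cα displacement is strictly below the
chosen cutoff. Predictions are scored with residue accuracy and the
Matthews correlation coefficient; datasets are evaluated by model-level
k-fold cross-validation with per-fold Z-scoring and CRF training.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from resq import crf
from resq.cliques import clique_tree_from_graph  # noqa: F401  (re-export for pipelines)
from resq.errors import UndefinedValueError
from resq.graph import EDGE_CLASSES, build_graph, classify_edges
from resq.structure import StructureModel, assign_secondary_structure, superpose


@dataclass
class ConfusionTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def make_labels(model: StructureModel, native: StructureModel, ca_cutoff: float) -> np.ndarray:
    """Per-residue truth labels: 1 if displaced < ca_cutoff Å after superposition.

    Returns a float vector aligned with the model's residues; NaN marks
    residues absent from the native structure (unscored).
    """
    sup = superpose(model, native)
    labels = np.full(len(model), np.nan)
    scored = ~np.isnan(sup.per_residue_distance)
    labels[scored] = (sup.per_residue_distance[scored] < ca_cutoff).astype(float)
    return labels


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of scored residues whose label matches; NaN truth is unscored."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    scored = ~np.isnan(truth)
    n = int(scored.sum())
    if n == 0:
        raise UndefinedValueError("no scored residues: accuracy undefined")
    return float((pred[scored] == truth[scored]).sum() / n)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionTable:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    scored = ~np.isnan(truth)
    p, t = pred[scored], truth[scored]
    return ConfusionTable(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def mcc(table: ConfusionTable) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero.

    A zero factor in the denominator (e.g. tn = fn = 0 for an
    all-positive predictor) makes the coefficient undefined, not 0.
    """
    tp, fp, tn, fn = table.tp, table.fp, table.tn, table.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return None
    return float((tp * tn - fp * fn) / math.sqrt(denom_sq))


def paired_t_test(a: np.ndarray, b: np.ndarray) -> float | None:
    """Two-sided paired t-test p-value; None when differences have zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(a - b) == 0:
        return None
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# dataset records and cross-validation


@dataclass
class ModelRecord:
    """One model of a dataset: structure, raw (unnormalized) features, truth labels."""

    model_id: str
    structure: StructureModel
    features_raw: np.ndarray  # (n_residues, m), unnormalized
    labels: np.ndarray  # (n_residues,), ints (fully scored) — NaN rows excluded upstream
    ss: str | None = None  # secondary structure override


@dataclass
class CVConfig:
    neighbor_cutoff: float = 4.5
    ca_cutoff: float = 5.0
    edge_weights: dict[str, float] = field(default_factory=lambda: {c: 1.0 for c in EDGE_CLASSES})
    hyper: crf.SGDHyper = field(default_factory=crf.SGDHyper)
    seed: int = 0


@dataclass
class CVResult:
    fold_accuracy: list[float]
    model_accuracy: dict[str, float]
    mean_accuracy: float
    fold_assignment: dict[str, int]


def _zscore_matrix(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    zt = (train - mu) / sd_safe
    zs = (test - mu) / sd_safe
    zt[:, sd == 0] = 0.0
    zs[:, sd == 0] = 0.0
    return zt, zs


def build_record_instance(
    record: ModelRecord,
    neighbor_cutoff: float,
    features: np.ndarray,
    with_labels: bool = True,
) -> crf.GraphModelInstance:
    """Residue graph → classified edges → CRF instance for one model."""
    graph = build_graph(record.structure, neighbor_cutoff)
    ss = record.ss if record.ss is not None else assign_secondary_structure(record.structure)
    graph = classify_edges(graph, ss)
    return crf.build_instance(
        graph,
        features,
        labels=record.labels.astype(int) if with_labels else None,
        model_id=record.model_id,
    )


LINEAR_NEIGHBOR_CUTOFF = 1.0  # Å; below Cα spacing, so no distance edges form


def predict_linear_baseline(
    record: ModelRecord, features: np.ndarray, params: crf.CRFParameters
) -> crf.QualityPrediction:
    """The full pipeline degenerated to a 1.0 Å neighbor cutoff.

    At this cutoff the graph reduces to chain edges plus their one-pass
    shared-neighbor triangles, so cliques carry essentially no spatial
    neighborhood information.
    """
    inst = build_record_instance(record, LINEAR_NEIGHBOR_CUTOFF, features, with_labels=False)
    return crf.predict(inst, params)


def kfold_split(model_ids: list[str], k: int, seed: int) -> dict[str, int]:
    """Deterministic model-level fold assignment."""
    if len(model_ids) < k:
        raise ValueError(f"{len(model_ids)} models is fewer than {k} folds")
    rng = np.random.default_rng(seed)
    order = list(model_ids)
    rng.shuffle(order)
    return {mid: i % k for i, mid in enumerate(order)}


def cross_validate(dataset: list[ModelRecord], k: int = 5, config: CVConfig | None = None) -> CVResult:
    """Model-level k-fold CV: per-fold Z-scoring, CRF training, MAP scoring.

    The training folds alone determine feature normalization and CRF
    parameters; accuracy is residue-level, reported per model and per fold.
    """
    if config is None:
        config = CVConfig()
    folds = kfold_split([r.model_id for r in dataset], k, config.seed)

    fold_acc: list[float] = []
    model_acc: dict[str, float] = {}
    for fold in range(k):
        train_recs = [r for r in dataset if folds[r.model_id] != fold]
        test_recs = [r for r in dataset if folds[r.model_id] == fold]

        train_stack = np.vstack([r.features_raw for r in train_recs])
        mu = train_stack.mean(axis=0)
        sd = train_stack.std(axis=0, ddof=0)
        sd_safe = np.where(sd == 0, 1.0, sd)

        def norm(x: np.ndarray) -> np.ndarray:
            z = (x - mu) / sd_safe
            z[:, sd == 0] = 0.0
            return z

        train_instances = [
            build_record_instance(r, config.neighbor_cutoff, norm(r.features_raw))
            for r in train_recs
        ]
        params, _ = crf.train_sgd(
            train_instances,
            hyper=config.hyper,
            edge_weights=config.edge_weights,
            ca_cutoff=config.ca_cutoff,
            neighbor_cutoff=config.neighbor_cutoff,
        )

        correct = total = 0
        for r in test_recs:
            inst = build_record_instance(r, config.neighbor_cutoff, norm(r.features_raw))
            pred = crf.infer_map(inst, params)
            acc = accuracy(pred, r.labels.astype(float))
            model_acc[r.model_id] = acc
            correct += int((pred == r.labels).sum())
            total += len(r.labels)
        fold_acc.append(correct / total)

    return CVResult(
        fold_accuracy=fold_acc,
        model_accuracy=model_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        fold_assignment=folds,
    )


def compare_cutoffs(
    dataset: list[ModelRecord], cutoffs: list[float], config: CVConfig | None = None, k: int = 5
) -> dict[tuple[float, float], float]:
    """Percentage of models predicted better-or-equal under the larger cutoff.

    Runs CV once per neighbor cutoff (same fold split throughout) and, for
    every pair (large > small), reports 100 * fraction of models whose
    accuracy under the large cutoff is >= that under the small one.
    """
    if len(cutoffs) < 2:
        raise ValueError("need at least two neighbor cutoffs")
    if config is None:
        config = CVConfig()
    per_cutoff: dict[float, dict[str, float]] = {}
    for c in cutoffs:
        cfg = CVConfig(
            neighbor_cutoff=c,
            ca_cutoff=config.ca_cutoff,
            edge_weights=dict(config.edge_weights),
            hyper=config.hyper,
            seed=config.seed,
        )
        per_cutoff[c] = cross_validate(dataset, k=k, config=cfg).model_accuracy

    out: dict[tuple[float, float], float] = {}
    ids = [r.model_id for r in dataset]
    for small, large in itertools.combinations(sorted(cutoffs), 2):
        better = sum(1 for mid in ids if per_cutoff[large][mid] >= per_cutoff[small][mid])
        out[(large, small)] = 100.0 * better / len(ids)
    return out


def edge_weight_grid() -> list[dict[str, float]]:
    """The 6^5 = 7776-point grid: HH/BB/HB in 0.5..1.0, CHB/CC in 0.0..0.5, step 0.1."""
    hi = [round(0.5 + 0.1 * i, 1) for i in range(6)]
    lo = [round(0.0 + 0.1 * i, 1) for i in range(6)]
    grid = []
    for hh, bb, hb, chb, cc in itertools.product(hi, hi, hi, lo, lo):
        grid.append({"HH": hh, "BB": bb, "HB": hb, "CHB": chb, "CC": cc})
    return grid


@dataclass
class GridSearchResult:
    best_weights: list[dict[str, float]]  # all co-optima
    best_accuracy: float
    surface: list[tuple[dict[str, float], float]]


def grid_search_edge_weights(
    dataset: list[ModelRecord],
    config: CVConfig | None = None,
    k: int = 5,
    grid: list[dict[str, float]] | None = None,
) -> GridSearchResult:
    """CV accuracy over a grid of edge-class weights; ties report all co-optima.

    ``grid`` defaults to the full 7776-point grid; pass a subset for
    exploratory runs (each point costs a full cross-validation).
    """
    if config is None:
        config = CVConfig()
    if grid is None:
        grid = edge_weight_grid()
    surface: list[tuple[dict[str, float], float]] = []
    for w in grid:
        cfg = CVConfig(
            neighbor_cutoff=config.neighbor_cutoff,
            ca_cutoff=config.ca_cutoff,
            edge_weights=dict(w),
            hyper=config.hyper,
            seed=config.seed,
        )
        acc = cross_validate(dataset, k=k, config=cfg).mean_accuracy
        surface.append((dict(w), acc))
    best = max(acc for _, acc in surface)
    co_optima = [w for w, acc in surface if acc == best]
    return GridSearchResult(best_weights=co_optima, best_accuracy=best, surface=surface)
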