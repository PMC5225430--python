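"""Per-residue feature vectors.

The default schema has 25 features: contact order, alignment-column
statistics and log/ratio transforms are computed here; scores produced by
external programs (energy/stereochemistry/alignment scorers) are ingested
from a TSV and never re-implemented. All values are Z-scored against the
training-set distribution (population standard deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import substitution_matrices

from resq.errors import FormatError, SchemaError
from resq.structure import StructureModel

logger = logging.getLogger(__name__)

LOG_FLOOR = 1e-6

#: (name, is_local, is_ingested)
_DEFAULT_FEATURES: tuple[tuple[str, bool, bool], ...] = (
    ("anolea1", False, True),
    ("anolea2", False, True),
    ("dope", False, True),
    ("tap", False, True),
    ("procheck_disallowed", False, True),
    ("verify3d_local", True, True),
    ("verify3d_global", False, True),
    ("verify3d_l2", False, False),
    ("log_verify3d_l2", False, False),
    ("mutation_score", True, False),
    ("gap_ratio", True, False),
    ("conservation", True, False),
    ("prss", False, True),
    ("spad_local", True, True),
    ("spad_global", False, True),
    ("log_spad", False, False),
    ("log_lspad_ratio", True, False),
    ("contact_order", False, False),
    ("relative_contact_order", False, False),
    ("model_length", False, False),
    ("aligned_length", False, True),
    ("ga341", False, True),
    ("pg", False, True),
    ("proq_maxsub", False, True),
    ("proq_lg", False, True),
)

#: forward-selected 5-feature view
SUBSET5 = ("verify3d_local", "log_spad", "log_verify3d_l2", "gap_ratio", "log_lspad_ratio")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    local: bool  # varies per residue (vs constant across a model)
    ingested: bool  # read from an external score table (vs computed here)


@dataclass
class FeatureSchema:
    features: tuple[FeatureDef, ...] = field(
        default_factory=lambda: tuple(FeatureDef(*f) for f in _DEFAULT_FEATURES)
    )

    def __post_init__(self) -> None:
        names = self.names
        if len(names) != len(set(names)):
            raise SchemaError("duplicate feature names")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def local_names(self) -> list[str]:
        return [f.name for f in self.features if f.local]

    @property
    def subset5(self) -> list[str]:
        return list(SUBSET5)

    def __len__(self) -> int:
        return len(self.features)


def default_schema() -> FeatureSchema:
    return FeatureSchema()


@dataclass
class FeatureTable:
    """residues x features values with normalization bookkeeping."""

    values: pd.DataFrame  # index = residue_index, columns = schema names
    schema: FeatureSchema
    normalized: bool = False
    means: pd.Series | None = None
    stds: pd.Series | None = None
    imputed_columns: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise SchemaError(f"unknown feature names: {missing}")
        sub_defs = tuple(f for f in self.schema.features if f.name in names)
        return FeatureTable(
            values=self.values[names].copy(),
            schema=FeatureSchema(features=sub_defs),
            normalized=self.normalized,
            means=None if self.means is None else self.means[names],
            stds=None if self.stds is None else self.stds[names],
            imputed_columns=[c for c in self.imputed_columns if c in names],
        )


def compute_contact_order(
    model: StructureModel, contact_cutoff: float = 8.0, min_separation: int = 2
) -> tuple[float, float]:
    """Mean sequence separation of Cα contacts, and its length-normalized version.

    A contact is a residue pair within ``contact_cutoff`` Å with sequence
    separation >= ``min_separation``. Zero contacts gives (0, 0).
    """
    coords = model.coords
    idx = model.indices
    n = len(model)
    seps = []
    for a in range(n):
        for b in range(a + 1, n):
            sep = abs(int(idx[b]) - int(idx[a]))
            if sep < min_separation:
                continue
            if np.linalg.norm(coords[a] - coords[b]) <= contact_cutoff:
                seps.append(sep)
    if not seps:
        logger.warning("model %s has no contacts at %.1f Å; contact order set to 0",
                       model.model_id, contact_cutoff)
        return 0.0, 0.0
    co = float(np.mean(seps))
    return co, co / n


_BLOSUM45 = substitution_matrices.load("BLOSUM45")


def blosum45(a: str, b: str) -> float:
    """BLOSUM45 substitution score for a pair of one-letter residue codes."""
    try:
        return float(_BLOSUM45[a.upper(), b.upper()])
    except (KeyError, IndexError):
        return float(_BLOSUM45["X", "X"])


def read_alignment(fasta_text: str) -> list[tuple[str, str]]:
    """Aligned FASTA → list of (id, sequence); all sequences equal length."""
    try:
        aln = AlignIO.read(StringIO(fasta_text), "fasta")
    except ValueError as exc:
        raise FormatError(f"bad aligned FASTA: {exc}") from exc
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def compute_msa_features(
    sequences: list[str], target_row: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column statistics mapped onto the target sequence's residues.

    For every column where the target row holds a residue (not a gap):
    mutation score = mean BLOSUM45 score over all unordered pairs of
    non-gap residues in the column; gap ratio = fraction of gap rows;
    conservation = count of the most abundant residue type / total rows.
    """
    if not sequences:
        raise FormatError("empty alignment")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise FormatError("ragged alignment: sequences differ in length")
    target = sequences[target_row]

    mut, gaps, cons = [], [], []
    for col in range(width):
        if target[col] in "-.":
            continue
        column = [s[col] for s in sequences]
        residues = [c for c in column if c not in "-."]
        n_gap = len(column) - len(residues)
        gaps.append(n_gap / len(column))
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        cons.append(max(counts.values()) / len(column))
        pair_scores = [
            blosum45(residues[i], residues[j])
            for i in range(len(residues))
            for j in range(i + 1, len(residues))
        ]
        mut.append(float(np.mean(pair_scores)) if pair_scores else 0.0)
    return np.array(mut), np.array(gaps), np.array(cons)


def _safe_log(x: np.ndarray | float, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < LOG_FLOOR):
        logger.warning("non-positive argument to log(%s); clamped to %g", what, LOG_FLOOR)
    return np.log(np.maximum(arr, LOG_FLOOR))


def derived_transforms(table: FeatureTable) -> FeatureTable:
    """Fill the composite columns from their raw ingredients.

    verify3d_l2 = verify3d_global / L^2, log_verify3d_l2 = log of that,
    log_spad = log(spad_global), log_lspad_ratio = log(spad_local /
    (spad_global + 1)). Natural logs; arguments floored at 1e-6.
    """
    df = table.values.copy()
    required = ["verify3d_global", "spad_global", "spad_local", "model_length"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"derived transforms need column {col!r}")
    length = df["model_length"].to_numpy(dtype=float)
    v3d = df["verify3d_global"].to_numpy(dtype=float)
    df["verify3d_l2"] = v3d / length**2
    df["log_verify3d_l2"] = _safe_log(v3d / length**2, "verify3d/L^2")
    df["log_spad"] = _safe_log(df["spad_global"].to_numpy(dtype=float), "spad")
    ratio = df["spad_local"].to_numpy(dtype=float) / (df["spad_global"].to_numpy(dtype=float) + 1.0)
    df["log_lspad_ratio"] = _safe_log(ratio, "lspad/(spad+1)")
    return FeatureTable(values=df, schema=table.schema, normalized=False,
                        imputed_columns=list(table.imputed_columns))


def ingest_external_scores(
    tsv_text: str, schema: FeatureSchema, residue_indices: list[int]
) -> FeatureTable:
    """Read an external score table into a (partial) feature table.

    Dialect: first column ``residue_index`` (or the literal key ``MODEL``
    for per-model rows, broadcast to all residues); remaining columns must
    be schema feature names. Missing ingested columns are left NaN and
    flagged for mean-imputation at normalization time.
    """
    df = pd.read_csv(StringIO(tsv_text), sep="\t", dtype={0: str})
    if df.columns[0] != "residue_index":
        raise FormatError("first column must be 'residue_index'")
    unknown = [c for c in df.columns[1:] if c not in schema.names]
    if unknown:
        raise SchemaError(f"unknown feature columns: {unknown}")

    out = pd.DataFrame(index=pd.Index(residue_indices, name="residue_index"),
                       columns=schema.names, dtype=float)

    model_rows = df[df["residue_index"] == "MODEL"]
    res_rows = df[df["residue_index"] != "MODEL"].copy()
    for col in df.columns[1:]:
        vals = model_rows[col].dropna()
        if len(vals) > 1:
            raise FormatError(f"multiple MODEL rows for column {col!r}")
        if len(vals) == 1:
            out[col] = float(vals.iloc[0])
    if not res_rows.empty:
        try:
            res_rows["residue_index"] = res_rows["residue_index"].astype(int)
        except ValueError as exc:
            raise FormatError(f"non-integer residue_index: {exc}") from exc
        extra = set(res_rows["residue_index"]) - set(residue_indices)
        if extra:
            raise FormatError(f"score rows for unknown residues: {sorted(extra)}")
        res_rows = res_rows.set_index("residue_index")
        if len(res_rows) not in (0, len(residue_indices)):
            raise FormatError(
                f"per-residue rows ({len(res_rows)}) do not cover the model "
                f"({len(residue_indices)} residues)"
            )
        for col in res_rows.columns:
            if res_rows[col].notna().any():
                out.loc[res_rows.index, col] = res_rows[col].astype(float).to_numpy()

    imputed = [f.name for f in schema.features if f.ingested and out[f.name].isna().all()]
    if imputed:
        logger.warning("ingested columns missing from score table, will impute: %s", imputed)
    return FeatureTable(values=out, schema=schema, imputed_columns=imputed)


def zscore_fit_transform(
    train: FeatureTable, *others: FeatureTable
) -> tuple[FeatureTable, ...]:
    """Z-score all tables using mean/std fitted on the training table only.

    Population standard deviation; zero-variance features map to 0
    everywhere; NaNs (missing / imputed) become 0 (= the training mean).
    """
    if train.values.empty:
        raise ValueError("empty training table")
    means = train.values.mean(axis=0, skipna=True)
    stds = train.values.std(axis=0, ddof=0, skipna=True)
    means = means.fillna(0.0)
    zero_var = (stds == 0) | stds.isna()
    if zero_var.any():
        logger.warning("zero-variance features mapped to 0: %s", list(stds.index[zero_var]))
    safe = stds.copy()
    safe[zero_var] = 1.0

    out = []
    for table in (train, *others):
        z = (table.values - means) / safe
        z.loc[:, zero_var[zero_var].index] = 0.0
        z = z.fillna(0.0)
        out.append(
            FeatureTable(values=z, schema=table.schema, normalized=True,
                         means=means.copy(), stds=stds.copy(),
                         imputed_columns=list(table.imputed_columns))
        )
    return tuple(out)
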