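"""Cα-trace structure models.

Reads single-chain PDB coordinate files down to an ordered Cα trace,
performs least-squares rigid superposition of two traces, and assigns a
coarse per-residue secondary-structure code (helix / strand / coil) from
Cα geometry alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from resq.errors import InsufficientOverlapError, PDBParseError, ResqError

logger = logging.getLogger(__name__)

SS_ALPHABET = frozenset("HBC")


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace."""

    index: int
    name: str
    ca: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        if self.ca.shape != (3,):
            raise ValueError("ca must be a 3-vector")


@dataclass
class StructureModel:
    """An ordered Cα trace for a single chain.

    Residue indices are strictly increasing; every residue carries exactly
    one Cα coordinate.
    """

    residues: list[Residue]
    model_id: str = "model"
    chain_id: str = " "

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a structure model needs at least 2 residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.residues]

    def position_of(self, residue_index: int) -> int:
        """List position of a residue index; raises KeyError if absent."""
        for pos, r in enumerate(self.residues):
            if r.index == residue_index:
                return pos
        raise KeyError(residue_index)


@dataclass
class Superposition:
    """Result of least-squares rigid alignment of a model onto a native trace.

    ``per_residue_distance`` is aligned with the model's residue list; NaN
    marks residues absent from the native structure.
    """

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    per_residue_distance: np.ndarray  # (len(model),), Å; NaN where unpaired
    rmsd: float
    shared_indices: list[int] = field(default_factory=list)


def read_model(pdb_text: str, chain: str | None = None, model_id: str = "model") -> StructureModel:
    """Parse ATOM records of a PDB file into a Cα trace.

    Only one chain is read (``chain`` if given, else the first chain seen).
    The first alternate location of each Cα is kept; HETATM records are
    ignored; residues with ATOM records but no Cα are dropped with a
    warning.
    """
    if not pdb_text.strip():
        raise PDBParseError("empty PDB input")

    selected_chain: str | None = chain
    seen_residues: dict[tuple[int, str], str] = {}  # (resseq, icode) -> resname
    ca_atoms: dict[tuple[int, str], np.ndarray] = {}
    order: list[tuple[int, str]] = []

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith("ENDMDL"):
            break  # first NMR/trajectory model only
        if not line.startswith("ATOM"):
            continue
        try:
            atom_name = line[12:16].strip()
            altloc = line[16:17]
            resname = line[17:20].strip()
            chain_id = line[21:22]
            resseq = int(line[22:26])
            icode = line[26:27]
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc

        if selected_chain is None:
            selected_chain = chain_id
        if chain_id != selected_chain:
            continue

        key = (resseq, icode)
        if key not in seen_residues:
            seen_residues[key] = resname
            order.append(key)
        if atom_name == "CA" and altloc in (" ", "A") and key not in ca_atoms:
            ca_atoms[key] = np.array([x, y, z])

    if not ca_atoms:
        raise PDBParseError(
            f"no CA atoms found in chain {selected_chain!r}"
            if selected_chain is not None
            else "no ATOM records found"
        )

    residues: list[Residue] = []
    kept_keys: list[tuple[int, str]] = []
    for key in order:
        if key in ca_atoms:
            kept_keys.append(key)
        else:
            logger.warning(
                "residue %s%s (%s) has no CA atom; dropped",
                key[0], key[1].strip(), seen_residues[key],
            )

    resseqs = [k[0] for k in kept_keys]
    has_icodes = any(k[1].strip() for k in kept_keys)
    monotone = all(b > a for a, b in zip(resseqs, resseqs[1:]))
    if has_icodes or not monotone:
        logger.warning("insertion codes or non-monotone numbering; residues renumbered 1..N")
        numbering = range(1, len(kept_keys) + 1)
    else:
        numbering = resseqs

    for new_index, key in zip(numbering, kept_keys):
        residues.append(Residue(index=new_index, name=seen_residues[key], ca=ca_atoms[key]))

    if len(residues) < 2:
        raise PDBParseError(f"fewer than 2 residues with CA atoms in chain {selected_chain!r}")

    return StructureModel(residues=residues, model_id=model_id, chain_id=selected_chain or " ")


def to_pdb(model: StructureModel, bfactors: np.ndarray | None = None) -> str:
    """Render a Cα trace as PDB ATOM records (one CA per residue)."""
    if bfactors is not None and len(bfactors) != len(model):
        raise ValueError("bfactors length must equal residue count")
    chain = model.chain_id if model.chain_id.strip() else "A"
    lines = []
    for serial, res in enumerate(model.residues, start=1):
        b = 0.0 if bfactors is None else float(bfactors[serial - 1])
        x, y, z = res.ca
        lines.append(
            f"ATOM  {serial:5d}  CA  {res.name:<3s} {chain}{res.index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``moving`` onto ``fixed`` (SVD route)."""
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    return rot, trans


def superpose(model: StructureModel, native: StructureModel) -> Superposition:
    """Least-squares superposition of ``model`` onto ``native`` over shared residues.

    All residue indices present in both structures enter the fit; per-residue
    distances are Euclidean Cα–Cα distances after the fit.
    """
    native_pos = {r.index: i for i, r in enumerate(native.residues)}
    shared = [r.index for r in model.residues if r.index in native_pos]
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared residues between model and native; need >= 3"
        )

    mc = model.coords
    nc = native.coords
    model_pos = {r.index: i for i, r in enumerate(model.residues)}
    p = np.array([mc[model_pos[i]] for i in shared])
    q = np.array([nc[native_pos[i]] for i in shared])

    rot, trans = _kabsch(p, q)
    moved = mc @ rot.T + trans

    dists = np.full(len(model), np.nan)
    for i in shared:
        mp = model_pos[i]
        dists[mp] = np.linalg.norm(moved[mp] - nc[native_pos[i]])
    paired = dists[~np.isnan(dists)]
    rmsd = float(np.sqrt(np.mean(paired**2)))
    return Superposition(
        rotation=rot,
        translation=trans,
        per_residue_distance=dists,
        rmsd=rmsd,
        shared_indices=shared,
    )


# Cα-geometry windows. An ideal alpha helix (1.5 Å rise, 100 deg/residue,
# 2.3 Å radius) gives d(i,i+3) ~ 5.05 Å and d(i,i+4) ~ 6.20 Å; an extended
# strand gives d(i,i+2) ~ 6.6-7.1 Å.
_HELIX_D13 = (4.4, 5.8)
_HELIX_D14 = (5.2, 7.0)
_STRAND_D02_MIN = 6.4


def assign_secondary_structure(model: StructureModel, override: str | None = None) -> str:
    """Per-residue secondary structure codes over {H, B, C}.

    The default assignment uses only Cα geometry (i→i+3 / i→i+4 distance
    windows for helices, i→i+2 extension for strands); anything else is
    coil. A precomputed ``override`` string replaces the internal method.
    """
    n = len(model)
    if override is not None:
        if len(override) != n:
            raise ValueError(
                f"secondary structure override has length {len(override)}, model has {n} residues"
            )
        bad = set(override) - SS_ALPHABET
        if bad:
            raise ValueError(f"unknown secondary structure codes: {sorted(bad)}")
        return override

    coords = model.coords
    helix = np.zeros(n, dtype=bool)
    strand = np.zeros(n, dtype=bool)

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    for i in range(n - 4):
        if _HELIX_D13[0] <= d(i, i + 3) <= _HELIX_D13[1] and _HELIX_D14[0] <= d(i, i + 4) <= _HELIX_D14[1]:
            helix[i : i + 5] = True
    for i in range(n - 2):
        if d(i, i + 2) >= _STRAND_D02_MIN:
            strand[i : i + 3] = True

    out = []
    for i in range(n):
        if helix[i]:
            out.append("H")
        elif strand[i]:
            out.append("B")
        else:
            out.append("C")
    return "".join(out)
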