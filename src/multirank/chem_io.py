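"""Molecule, activity-table and sparse-fingerprint I/O.

Structure handling is a deliberately minimal normalization: largest
fragment, aromaticity perception and hydrogen-count bookkeeping (RDKit
backed).  It stands in for a full standardization pipeline
(neutralization, tautomer canonicalization), which is out of scope and
documented as such in docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .fingerprints import SparseFingerprint

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

BondOrder = int | str  # 1, 2, 3 or "ar"

_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    "ar": Chem.BondType.AROMATIC,
}


@dataclass(frozen=True)
class Molecule:
    """A light molecular graph: atoms, bonds, and provenance.

    ``atoms`` holds ``(element symbol, formal charge, attached-H count)``
    triples; ``bonds`` holds ``(i, j, order)`` with order in
    ``{1, 2, 3, "ar"}``.
    """

    id: str
    atoms: tuple[tuple[str, int, int], ...]
    bonds: tuple[tuple[int, int, BondOrder], ...]
    provenance: str = "unknown"
    props: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"molecule {self.id}: invalid bond ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.id}: duplicate bond {key}")
            seen.add(key)
            if order not in (1, 2, 3, "ar"):
                raise ValueError(f"molecule {self.id}: bad bond order {order!r}")

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)


class MoleculeList(list):
    """A list of molecules that remembers how many records were skipped."""

    skipped: int = 0


def _from_rdkit(mol: Chem.Mol, mol_id: str, provenance: str, props=None) -> Molecule:
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            order: BondOrder = "ar"
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Molecule(mol_id, atoms, tuple(bonds), provenance, dict(props or {}))


def _to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for symbol, charge, hs in mol.atoms:
        atom = Chem.Atom(symbol)
        atom.SetFormalCharge(charge)
        atom.SetNumExplicitHs(hs)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in mol.bonds:
        rw.AddBond(int(i), int(j), _RD_BOND[order])
        if order == "ar":
            rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
            rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def read_smiles(path: str | Path) -> MoleculeList:
    """Read a ``SMILES<whitespace>id`` file (one record per line).

    Unparsable lines are skipped and counted on the returned list's
    ``skipped`` attribute; an empty result is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = MoleculeList()
    skipped = 0
    seen_ids: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            logger.warning("%s:%d: missing id, skipped", path, lineno)
            skipped += 1
            continue
        smiles, mol_id = parts[0], parts[1]
        rd = Chem.MolFromSmiles(smiles)
        if rd is None:
            logger.warning("%s:%d: unparsable SMILES %r, skipped", path, lineno, smiles)
            skipped += 1
            continue
        if mol_id in seen_ids:
            raise ValueError(f"{path}: duplicate molecule id {mol_id!r}")
        seen_ids.add(mol_id)
        out.append(_from_rdkit(rd, mol_id, "smiles"))
    out.skipped = skipped
    if not out:
        raise ValueError(f"{path}: no parsable SMILES records")
    return out


def read_sdf(path: str | Path) -> MoleculeList:
    """Read a V2000 SDF; property fields are retained as metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    out = MoleculeList()
    skipped = 0
    seen_ids: set[str] = set()
    for i, rd in enumerate(supplier):
        if rd is None:
            logger.warning("%s: record %d unparsable, skipped", path, i)
            skipped += 1
            continue
        mol_id = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"mol{i}"
        if mol_id in seen_ids:
            raise ValueError(f"{path}: duplicate molecule id {mol_id!r}")
        seen_ids.add(mol_id)
        out.append(_from_rdkit(rd, mol_id, "sdf", rd.GetPropsAsDict()))
    out.skipped = skipped
    if not out:
        raise ValueError(f"{path}: no parsable SDF records")
    return out


@dataclass
class ActivityTable:
    """Per-compound activity values over an ordered target list.

    ``frame`` is indexed by compound id; values are either binary (0/1)
    or real pK_i, as indicated by ``mode``.
    """

    targets: list[str]
    frame: pd.DataFrame
    mode: str  # "binary" | "pki"
    cutoff: float | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    def binary_profiles(self, cutoff: float | None = None) -> np.ndarray:
        """Binary (n_compounds, m) matrix; pK_i >= cutoff counts as active."""
        if self.mode == "binary":
            return self.frame.to_numpy(dtype=int)
        cut = self.cutoff if cutoff is None else cutoff
        if cut is None:
            raise ValueError("pki table needs a cutoff")
        return (self.frame.to_numpy(dtype=float) >= cut).astype(int)

    def profile(self, compound_id: str, cutoff: float | None = None) -> tuple[int, ...]:
        row = self.frame.loc[compound_id]
        if self.mode == "binary":
            return tuple(int(v) for v in row)
        cut = self.cutoff if cutoff is None else cutoff
        return tuple(int(v >= cut) for v in row)


def read_activity_table(
    path: str | Path, mode: str = "binary", cutoff: float | None = None
) -> ActivityTable:
    """Read a TSV activity table (``id<TAB>target1<TAB>...``).

    In ``pki`` mode a cutoff is required and values >= cutoff become
    active; binary mode validates every cell is 0 or 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if mode not in ("binary", "pki"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pki" and cutoff is None:
        raise ValueError("pki mode requires a cutoff")
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need an id column and at least one target")
    id_col = frame.columns[0]
    targets = list(frame.columns[1:])
    frame = frame.set_index(id_col)
    for col in targets:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        frame[col] = converted
    if mode == "binary":
        values = frame.to_numpy(dtype=float)
        if not np.isin(values, (0.0, 1.0)).all():
            i, j = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
            raise ValueError(
                f"{path}: binary cell outside {{0,1}} at row {frame.index[i]!r}, "
                f"column {targets[j]!r}"
            )
        frame = frame.astype(int)
    return ActivityTable(targets, frame, mode, cutoff)


def _format_value(v: float) -> str:
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def write_sparse_fingerprints(
    records: Iterable[tuple[SparseFingerprint, float]], path: str | Path
) -> None:
    """Write labeled fingerprints in the libsvm-style sparse text dialect.

    One record per line: ``label index:value ...`` with 0-based, strictly
    ascending feature indices.  A leading comment records the dimension
    and normalization flag so round trips are bit-exact.
    """
    records = list(records)
    path = Path(path)
    with path.open("w") as fh:
        if records:
            fp0 = records[0][0]
            fh.write(f"# dim={fp0.dim} normalized={int(fp0.normalized)}\n")
        for fp, label in records:
            tokens = [_format_value(label)]
            tokens += [f"{i}:{_format_value(v)}" for i, v in zip(fp.indices, fp.values)]
            fh.write(" ".join(tokens) + "\n")


def read_sparse_fingerprints(
    path: str | Path, dim: int = 2**20
) -> list[tuple[SparseFingerprint, float]]:
    """Read the sparse text dialect written by :func:`write_sparse_fingerprints`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    normalized = False
    out: list[tuple[SparseFingerprint, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                key, _, value = token.partition("=")
                if key == "dim":
                    dim = int(value)
                elif key == "normalized":
                    normalized = bool(int(value))
            continue
        tokens = line.split()
        label = float(tokens[0])
        indices: list[int] = []
        values: list[float] = []
        for token in tokens[1:]:
            idx_s, _, val_s = token.partition(":")
            idx = int(idx_s)
            if indices and idx <= indices[-1]:
                raise ValueError(
                    f"{path}:{lineno}: unsorted or duplicate feature index {idx}"
                )
            indices.append(idx)
            values.append(float(val_s))
        fp = SparseFingerprint(
            np.asarray(indices, dtype=np.int64),
            np.asarray(values, dtype=float),
            dim=dim,
            normalized=normalized,
        )
        out.append((fp, label))
    return out


def normalize_structure(mol: Molecule) -> Molecule:
    """Keep the largest fragment, perceive aromaticity, count hydrogens.

    The output atom order is the RDKit canonical order, so two input
    orderings of the same molecule normalize identically, and the
    operation is idempotent.  Equal-size fragment ties keep the fragment
    with more heavy atoms, then the lexicographically smallest canonical
    SMILES (logged).
    """
    rd = _to_rdkit(mol)
    frags = Chem.GetMolFrags(rd, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        keyed = sorted(
            ((-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f), k), f)
            for k, f in enumerate(frags)
        )
        if keyed[0][0][0] == keyed[1][0][0]:
            logger.info("molecule %s: equal-size fragment tie, kept %s",
                        mol.id, keyed[0][0][1])
        rd = keyed[0][1]
    Chem.SetAromaticity(rd)
    ranks = list(Chem.CanonicalRankAtoms(rd))
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    rd = Chem.RenumberAtoms(rd, order)
    return _from_rdkit(rd, mol.id, mol.provenance, mol.props)
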