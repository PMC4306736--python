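"""Hashed circular (ECFP-style) fingerprints and the cosine kernel.

Atom environments are hashed iteratively for ``bond_diameter/2`` rounds
with a deterministic 32-bit hash (blake2b) and folded modulo the hash
space (2^20 by default).  Length-normalizing the resulting sparse
vectors makes the plain dot product equal the cosine kernel
k_cos(x_i, x_j) = x_i^T x_j / (||x_i|| ||x_j||), which keeps pairwise
similarities in [0, 1] regardless of molecule size.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .chem_io import Molecule

_BOND_CODE = {1: 1, 2: 2, 3: 3, "ar": 4}


@dataclass(frozen=True)
class SparseFingerprint:
    """A sparse non-negative feature vector with strictly ascending indices."""

    indices: np.ndarray
    values: np.ndarray
    dim: int = 2**20
    normalized: bool = False

    def __post_init__(self):
        indices = np.asarray(self.indices, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "indices", indices)
        object.__setattr__(self, "values", values)
        if indices.shape != values.shape:
            raise ValueError("indices and values must have equal length")
        if indices.size:
            if indices[0] < 0 or indices[-1] >= self.dim:
                raise ValueError("feature index out of range")
            if not (np.diff(indices) > 0).all():
                raise ValueError("feature indices must be strictly increasing")
            if not (values > 0).all():
                raise ValueError("feature values must be positive")
        if self.normalized and abs(self.norm() - 1.0) > 1e-9:
            raise ValueError("normalized flag set but Euclidean norm is not 1")

    @property
    def nnz(self) -> int:
        return int(self.indices.size)

    def norm(self) -> float:
        return float(np.sqrt(np.dot(self.values, self.values)))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SparseFingerprint)
            and self.dim == other.dim
            and self.normalized == other.normalized
            and np.array_equal(self.indices, other.indices)
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self):
        return hash((self.dim, self.normalized, self.indices.tobytes(),
                     self.values.tobytes()))


@dataclass(frozen=True)
class FingerprintConfig:
    """ECFP parameters: bond diameter (even), hash-space size, value mode."""

    bond_diameter: int = 6
    dim: int = 2**20
    counts: bool = False

    def __post_init__(self):
        if self.bond_diameter < 0 or self.bond_diameter % 2:
            raise ValueError("bond_diameter must be even and non-negative")
        if self.dim <= 0 or self.dim & (self.dim - 1):
            raise ValueError("dim must be a power of two")


def _stable_hash(payload: tuple) -> int:
    """Deterministic 32-bit hash of a nested tuple of ints/strings."""
    digest = hashlib.blake2b(repr(payload).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def _ring_atoms(mol: "Molecule") -> list[bool]:
    graph = nx.Graph()
    graph.add_nodes_from(range(mol.num_atoms))
    graph.add_edges_from((i, j) for i, j, _ in mol.bonds)
    bridges = {frozenset(e) for e in nx.bridges(graph)}
    in_ring = [False] * mol.num_atoms
    for i, j, _ in mol.bonds:
        if frozenset((i, j)) not in bridges:
            in_ring[i] = in_ring[j] = True
    return in_ring


def initial_atom_invariants(mol: "Molecule") -> list[int]:
    """Round-0 atom codes: element, heavy degree, H count, charge, ring flag."""
    degree = [0] * mol.num_atoms
    for i, j, _ in mol.bonds:
        degree[i] += 1
        degree[j] += 1
    in_ring = _ring_atoms(mol)
    return [
        _stable_hash(("atom", symbol, degree[a], hs, charge, in_ring[a]))
        for a, (symbol, charge, hs) in enumerate(mol.atoms)
    ]


def ecfp(mol: "Molecule", cfg: FingerprintConfig = FingerprintConfig()) -> SparseFingerprint:
    """Circular fingerprint by iterative neighborhood hashing.

    Each round every atom's code becomes a hash of its previous code and
    the sorted (bond order, neighbor code) pairs; codes from every round
    (round 0 included) are folded modulo ``cfg.dim``.  The result is
    independent of the input atom order.
    """
    if mol.num_atoms == 0:
        warnings.warn(f"molecule {mol.id}: empty, empty fingerprint")
        return SparseFingerprint(np.empty(0, np.int64), np.empty(0), dim=cfg.dim)
    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(mol.num_atoms)]
    for i, j, order in mol.bonds:
        code = _BOND_CODE[order]
        neighbors[i].append((code, j))
        neighbors[j].append((code, i))
    codes = initial_atom_invariants(mol)
    all_codes: list[int] = list(codes)
    for _ in range(cfg.bond_diameter // 2):
        codes = [
            _stable_hash(
                ("env", codes[a], tuple(sorted((b, codes[n]) for b, n in neighbors[a])))
            )
            for a in range(mol.num_atoms)
        ]
        all_codes.extend(codes)
    folded = np.asarray(all_codes, dtype=np.int64) % cfg.dim
    if cfg.counts:
        indices, counts = np.unique(folded, return_counts=True)
        values = counts.astype(float)
    else:
        indices = np.unique(folded)
        values = np.ones(indices.size)
    return SparseFingerprint(indices, values, dim=cfg.dim)


def cosine_normalize(fp: SparseFingerprint) -> SparseFingerprint:
    """Scale to unit Euclidean length so dot products are cosine similarities."""
    if fp.nnz == 0:
        raise ValueError("cannot normalize an empty fingerprint (norm 0)")
    return replace(fp, values=fp.values / fp.norm(), normalized=True)


def dot(a: SparseFingerprint, b: SparseFingerprint) -> float:
    """Sparse merge-join dot product; cosine kernel on normalized inputs."""
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
    common, ia, ib = np.intersect1d(a.indices, b.indices, return_indices=True)
    if common.size == 0:
        return 0.0
    return float(np.dot(a.values[ia], b.values[ib]))
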