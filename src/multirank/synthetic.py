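"""Synthetic multi-target screening benchmarks with planted ground truth.

Each target owns a disjoint block of "pharmacophore" features.  A
compound with a given activity profile carries, for every target it is
active on, each feature of that target's block with probability
``activation_prob``; on top sit uniformly placed background bits (mean
``bits_per_compound`` per compound) and, as noise, every block feature
is flipped with probability ``background_noise``.  The per-target
ground-truth weight vector is the indicator of the target's block, so a
linear ranker can separate the designed profiles perfectly in the
noise-free limit.

Fingerprints are generated directly (no molecule graphs): every
downstream learner consumes sparse fingerprints only.  The default
design plants single-, dual- and triple-target actives plus decoys in
the overlap structure of a three-target confirmatory screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_DESIGN = {
    (1, 0, 0): 100, (0, 1, 0): 100, (0, 0, 1): 100,
    (1, 1, 0): 60, (1, 0, 1): 60, (0, 1, 1): 60,
    (1, 1, 1): 40,
    (0, 0, 0): 280,
}


def _default_blocks(m: int, block_size: int) -> tuple[tuple[int, ...], ...]:
    return tuple(
        tuple(range(k * block_size, (k + 1) * block_size)) for k in range(m)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults give the standard three-target benchmark."""

    m: int = 3
    dim: int = 2**12
    bits_per_compound: float = 20.0
    block_size: int = 30
    target_feature_blocks: tuple[tuple[int, ...], ...] | None = None
    activation_prob: float = 1.0
    background_noise: float = 0.0
    overlap_design: dict[tuple[int, ...], int] = field(
        default_factory=lambda: dict(DEFAULT_DESIGN)
    )
    seed: int = 0

    def __post_init__(self):
        blocks = self.target_feature_blocks
        if blocks is None:
            blocks = _default_blocks(self.m, self.block_size)
            object.__setattr__(self, "target_feature_blocks", blocks)
        if len(blocks) != self.m:
            raise ValueError("need one feature block per target")
        flat = [i for blk in blocks for i in blk]
        if len(set(flat)) != len(flat):
            raise ValueError("target feature blocks must be disjoint")
        if flat and max(flat) >= self.dim:
            raise ValueError("block feature index out of range")
        if not (0 <= self.activation_prob <= 1 and 0 <= self.background_noise <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        design = {tuple(int(v) for v in k): int(c)
                  for k, c in self.overlap_design.items()}
        if any(len(k) != self.m for k in design):
            raise ValueError("design profiles must have length m")
        if any(c < 0 for c in design.values()):
            raise ValueError("design counts must be non-negative")
        object.__setattr__(self, "overlap_design", design)

    @property
    def n_compounds(self) -> int:
        return sum(self.overlap_design.values())


@dataclass
class Benchmark:
    """Generated compounds: sparse fingerprints, profiles, ids, truth."""

    X: sp.csr_matrix
    profiles: np.ndarray  # (n, m) binary
    ids: list[str]
    true_weights: np.ndarray  # (m, dim) planted per-target models
    spec: SyntheticSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]


def make_benchmark(spec: SyntheticSpec) -> Benchmark:
    """Generate a benchmark; realized profile counts equal the design exactly."""
    if spec.n_compounds == 0:
        raise ValueError("design is empty")
    rng = np.random.default_rng(spec.seed)
    profile_rows = [
        profile for profile, count in sorted(spec.overlap_design.items())
        for _ in range(count)
    ]
    order = rng.permutation(len(profile_rows))
    profiles = np.asarray(profile_rows, dtype=int)[order]

    blocks = [np.asarray(blk, dtype=np.int64) for blk in spec.target_feature_blocks]
    block_union = (
        np.concatenate(blocks) if blocks and sum(len(b) for b in blocks)
        else np.empty(0, np.int64)
    )
    background_pool = np.setdiff1d(np.arange(spec.dim), block_union)

    rows, cols = [], []
    for i, profile in enumerate(profiles):
        on = np.zeros(spec.dim, dtype=bool)
        for k in range(spec.m):
            if profile[k]:
                blk = blocks[k]
                on[blk] = rng.random(blk.size) < spec.activation_prob
        if spec.background_noise > 0:
            flips = rng.random(block_union.size) < spec.background_noise
            on[block_union] ^= flips
        n_bg = rng.poisson(spec.bits_per_compound)
        n_bg = min(n_bg, background_pool.size)
        if n_bg:
            on[rng.choice(background_pool, size=n_bg, replace=False)] = True
        idx = np.nonzero(on)[0]
        rows.append(np.full(idx.size, i, dtype=np.int64))
        cols.append(idx)
    rows = np.concatenate(rows) if rows else np.empty(0, np.int64)
    cols = np.concatenate(cols) if len(cols) else np.empty(0, np.int64)
    X = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)),
        shape=(len(profiles), spec.dim),
    )
    true_weights = np.zeros((spec.m, spec.dim))
    for k, blk in enumerate(blocks):
        true_weights[k, blk] = 1.0
    ids = [f"cpd{i:05d}" for i in range(len(profiles))]
    return Benchmark(X, profiles, ids, true_weights, spec)


def profile_census(profiles) -> dict[tuple[int, ...], int]:
    """Exact counts per profile (all 2^m profiles reported, zeros included)."""
    profiles = np.asarray(profiles, dtype=int)
    if profiles.size == 0:
        return {}
    m = profiles.shape[1]
    census: dict[tuple[int, ...], int] = {}
    from itertools import product

    for p in product((0, 1), repeat=m):
        census[p] = 0
    for row in profiles:
        census[tuple(int(v) for v in row)] += 1
    return census


def write_benchmark(bench: Benchmark, out_dir: str | Path,
                    targets: list[str] | None = None) -> tuple[Path, Path]:
    """Write fingerprints (sparse text) and the activity TSV; round-trips."""
    from .chem_io import write_sparse_fingerprints
    from .fingerprints import SparseFingerprint

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fps_path = out_dir / "fingerprints.svml"
    act_path = out_dir / "activity.tsv"
    records = []
    X = bench.X.tocsr()
    for i in range(bench.n):
        row = X.getrow(i)
        fp = SparseFingerprint(row.indices.astype(np.int64), row.data,
                               dim=bench.spec.dim)
        records.append((fp, i))
    write_sparse_fingerprints(records, fps_path)
    targets = targets or [f"T{k + 1}" for k in range(bench.spec.m)]
    frame = pd.DataFrame(bench.profiles, columns=targets)
    frame.insert(0, "id", bench.ids)
    frame.to_csv(act_path, sep="\t", index=False)
    return fps_path, act_path
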