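"""Repeated-sampling evaluation protocol for multi-target screening.

One repetition: draw a profile-balanced training sample (from every
activity-profile subset, n = half the smallest subset of the same
single/dual/triple category), add sampled decoys, pick C by a
stratified 2-fold cross-validated grid search, fit the method, and
score the held-out compounds under two labelings of the same test set:
binary (main-target activity only, where the ranking error equals
1 - AUC) and graded (the same rank-score scheme used for training).
Repetitions share seeds across methods so comparisons are paired.

The trypsin-like protease protocol re-binarizes real pK_i values at a
sweep of activity cutoffs and uses stratified 50/50 train/test splits
(same label distribution in both halves) instead of decoy injection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from . import baselines
from .profile_encoding import EncodingScheme, binary_labels, encode_profile, srank_encode
from .ranksvm import RankSVM, build_pair_set, kpartite_error, rank_error

logger = logging.getLogger(__name__)

RANK_C_GRID = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
SVC_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)

METHODS = ("mtrank", "srank", "svc", "svm_lc", "mcsvm")


@dataclass
class ExperimentConfig:
    """Protocol settings; defaults follow the standard screening protocol."""

    method: str
    scheme: EncodingScheme
    repetitions: int = 20
    decoys_per_train: int = 1000
    cv_folds: int = 2
    C_grid: tuple[float, ...] | None = None
    seed: int = 0
    lc_factors: tuple[float, ...] | None = None
    protocol: str = "profile_balanced"  # or "stratified_split"
    # ranking-solver effort (cross-validation fits may be looser)
    tol: float = 1e-4
    max_iter: int = 400
    cv_tol: float = 3e-3
    cv_max_iter: int = 150

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.C_grid is None:
            self.C_grid = RANK_C_GRID if self.method in ("mtrank", "srank") else SVC_C_GRID
        if not self.C_grid:
            raise ValueError("C grid must be non-empty")
        if self.protocol not in ("profile_balanced", "stratified_split"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass
class ExperimentResult:
    """Per-repetition metrics plus aggregation helpers."""

    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        grouped = self.table.groupby("method")
        rows = {}
        for metric in ("rank_error_binary", "kpartite_error_graded"):
            agg = grouped[metric].agg(["mean", "std"])
            iqr = grouped[metric].quantile(0.75) - grouped[metric].quantile(0.25)
            rows[f"{metric}_mean"] = agg["mean"]
            rows[f"{metric}_sd"] = agg["std"]
            rows[f"{metric}_iqr"] = iqr
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# sampling


def group_by_profile(profiles: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    """Indices of active compounds grouped by exact activity profile."""
    profiles = np.asarray(profiles, dtype=int)
    groups: dict[tuple[int, ...], np.ndarray] = {}
    keys = [tuple(int(v) for v in row) for row in profiles]
    for key in sorted(set(keys)):
        if sum(key) > 0:
            groups[key] = np.asarray([i for i, k in enumerate(keys) if k == key])
    return groups


_CATEGORY_SIZE = {"single": 1, "dual": 2, "triple": 3}


def profile_balanced_sample(
    groups: Mapping[tuple[int, ...], Sequence[int]],
    category: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n = floor(min subset size / 2) from each subset of a category.

    Returns (train indices, remaining indices of the same category).
    """
    k = _CATEGORY_SIZE[category]
    subsets = {p: np.asarray(ids) for p, ids in groups.items() if sum(p) == k}
    if not subsets:
        raise ValueError(f"no profile subsets in category {category!r}")
    for p, ids in subsets.items():
        if ids.size < 2:
            raise ValueError(f"profile subset {p} has fewer than 2 compounds")
    n = min(ids.size for ids in subsets.values()) // 2
    train, rest = [], []
    for p in sorted(subsets):
        ids = subsets[p]
        picked = rng.choice(ids, size=n, replace=False)
        train.append(np.sort(picked))
        rest.append(np.setdiff1d(ids, picked))
    return np.concatenate(train), np.concatenate(rest)


def add_decoys(
    train_ids: np.ndarray,
    decoy_pool: Sequence[int],
    k: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Append k decoys sampled without replacement (all if the pool is short)."""
    rng = rng or np.random.default_rng()
    pool = np.asarray(decoy_pool)
    if pool.size < k:
        logger.warning("decoy pool (%d) smaller than requested %d: using all",
                       pool.size, k)
        picked = pool.copy()
    else:
        picked = np.sort(rng.choice(pool, size=k, replace=False))
    return np.concatenate([np.asarray(train_ids), picked])


# ---------------------------------------------------------------------------
# labeling and method dispatch


def label_test_sets(
    profiles: np.ndarray, scheme: EncodingScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Binary main-target labels and graded scheme scores for a test set."""
    profiles = np.asarray(profiles, dtype=int)
    binary = np.asarray(
        [binary_labels(p, scheme.main_targets) for p in profiles], dtype=int
    )
    graded = np.asarray([encode_profile(scheme, p) for p in profiles], dtype=int)
    return binary, graded


def _train_scores(method: str, profiles: np.ndarray, scheme: EncodingScheme) -> np.ndarray:
    if method in ("mtrank", "mcsvm"):
        return np.asarray([encode_profile(scheme, p) for p in profiles], dtype=int)
    if method == "srank":
        main = scheme.main_targets[0]
        return np.asarray([srank_encode(p, main) + 1 for p in profiles], dtype=int)
    # svc / svm_lc select C on the binary labeling
    return np.asarray([binary_labels(p, scheme.main_targets) for p in profiles],
                      dtype=int)


def _fit_predictor(method, X, profiles, scheme, C, cfg: ExperimentConfig,
                   seed: int, cv: bool):
    """Fit one method; returns a callable mapping X -> real-valued scores."""
    profiles = np.asarray(profiles, dtype=int)
    if method in ("mtrank", "srank"):
        scores = _train_scores(method, profiles, scheme)
        tol = cfg.cv_tol if cv else cfg.tol
        max_iter = cfg.cv_max_iter if cv else cfg.max_iter
        # the ranking C grid follows the original ranking-SVM software
        # convention (C times an *unnormalized* sum of pairwise slacks);
        # our objective divides the loss by the total pair weight W, so the
        # equivalent solver coefficient is C * W of this training set
        W = build_pair_set(scores).total_weight
        res = RankSVM(scores, X).fit(C=C * W, tol=tol, max_iter=max_iter,
                                     seed=seed)
        return res.predict
    if method == "svc":
        y = np.asarray([binary_labels(p, scheme.main_targets) for p in profiles])
        model = baselines.fit_svc(X, y, C, seed=seed)
        return model.decision_function
    if method == "svm_lc":
        factors = cfg.lc_factors
        if factors is None:
            factors = tuple(2.0 if k in scheme.main_targets else -1.0
                            for k in range(scheme.m))
        parts = []
        for k in range(scheme.m):
            model_k = baselines.fit_svc(X, profiles[:, k], C, seed=seed)
            parts.append((model_k, float(factors[k])))
        combined = baselines.combine(parts)
        return combined.decision_function
    if method == "mcsvm":
        scores = _train_scores(method, profiles, scheme)
        model = baselines.fit_mcsvm(X, scores, C, seed=seed)
        return lambda Xt: baselines.rank_by_mc(model, Xt)
    raise ValueError(f"unknown method {method!r}")


def _selection_metric(method: str):
    # ranking methods select C on the k-partite error of the graded labels;
    # the plain SVC uses the miss-ranked-pair fraction on binary labels
    return rank_error if method == "svc" else kpartite_error


def _stratified_folds(scores: np.ndarray, folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    assignment = np.empty(scores.size, dtype=int)
    offset = 0
    for v in np.unique(scores):
        idx = np.nonzero(scores == v)[0]
        idx = rng.permutation(idx)
        assignment[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    return [np.nonzero(assignment == f)[0] for f in range(folds)]


def grid_search_C(
    method: str,
    X,
    profiles: np.ndarray,
    scheme: EncodingScheme,
    grid: Sequence[float],
    folds: int = 2,
    rng: np.random.Generator | None = None,
    cfg: ExperimentConfig | None = None,
) -> float:
    """Pick C by stratified cross-validation; ties go to the smaller C."""
    if not len(grid):
        raise ValueError("C grid must be non-empty")
    grid = sorted(float(c) for c in grid)
    if len(grid) == 1:
        return grid[0]
    rng = rng or np.random.default_rng()
    cfg = cfg or ExperimentConfig(method=method, scheme=scheme)
    profiles = np.asarray(profiles, dtype=int)
    X = sp.csr_matrix(X)
    strat_scores = _train_scores(method, profiles, scheme)
    metric = _selection_metric(method)

    fold_idx = None
    for _ in range(10):
        candidate = _stratified_folds(strat_scores, folds, rng)
        ok = True
        for f in range(folds):
            val = candidate[f]
            tr = np.concatenate([candidate[g] for g in range(folds) if g != f])
            if (np.unique(strat_scores[tr]).size < 2
                    or np.unique(strat_scores[val]).size < 2):
                ok = False
                break
            if method == "svm_lc" and any(
                np.unique(profiles[tr][:, k]).size < 2 for k in range(scheme.m)
            ):
                ok = False
                break
        if ok:
            fold_idx = candidate
            break
    if fold_idx is None:
        raise ValueError("could not build stratified folds with every score level")

    best_c, best_err = None, np.inf
    for C in grid:
        errs = []
        for f in range(folds):
            val = fold_idx[f]
            tr = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            predictor = _fit_predictor(method, X[tr], profiles[tr], scheme, C,
                                       cfg, seed=0, cv=True)
            pred = predictor(X[val])
            if method == "svc":
                truth = np.asarray(
                    [binary_labels(p, scheme.main_targets) for p in profiles[val]]
                )
            else:
                truth = np.asarray(
                    [encode_profile(scheme, p) for p in profiles[val]]
                )
            errs.append(metric(pred, truth))
        mean_err = float(np.mean(errs))
        if mean_err < best_err - 1e-15:
            best_err, best_c = mean_err, C
    return best_c


# ---------------------------------------------------------------------------
# experiment driver


def _one_repetition(cfg: ExperimentConfig, X, profiles, rep: int):
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, rep)))
    profiles = np.asarray(profiles, dtype=int)
    n = profiles.shape[0]
    if cfg.protocol == "profile_balanced":
        groups = group_by_profile(profiles)
        categories = sorted({sum(p) for p in groups})
        train_parts = []
        for k in categories:
            name = {1: "single", 2: "dual", 3: "triple"}.get(k)
            if name is None:
                continue
            part, _ = profile_balanced_sample(groups, name, rng)
            train_parts.append(part)
        actives_train = np.concatenate(train_parts)
        decoy_pool = np.nonzero(profiles.sum(axis=1) == 0)[0]
        train_idx = add_decoys(actives_train, decoy_pool,
                               k=cfg.decoys_per_train, rng=rng)
    else:
        # stratified 50/50 split: same label distribution in both halves
        graded = np.asarray([encode_profile(cfg.scheme, p) for p in profiles])
        if not (graded > 0).any():
            raise ValueError("no active compounds at this labeling")
        train_parts = []
        for v in np.unique(graded):
            idx = rng.permutation(np.nonzero(graded == v)[0])
            take = idx.size // 2
            if take == 0:
                logger.warning("score level %d has a single compound: left in test", v)
            train_parts.append(np.sort(idx[:take]))
        train_idx = np.concatenate(train_parts)
    train_idx = np.sort(train_idx)
    test_idx = np.setdiff1d(np.arange(n), train_idx)

    C = grid_search_C(cfg.method, X[train_idx], profiles[train_idx], cfg.scheme,
                      cfg.C_grid, folds=cfg.cv_folds, rng=rng, cfg=cfg)
    predictor = _fit_predictor(cfg.method, X[train_idx], profiles[train_idx],
                               cfg.scheme, C, cfg, seed=0, cv=False)
    pred = predictor(X[test_idx])
    binary, graded = label_test_sets(profiles[test_idx], cfg.scheme)
    return {
        "repetition": rep,
        "method": cfg.method,
        "C": C,
        "rank_error_binary": rank_error(pred, binary),
        "kpartite_error_graded": kpartite_error(pred, graded),
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
    }


def run_experiment(cfg: ExperimentConfig, X, profiles) -> ExperimentResult:
    """Run the full repeated-sampling protocol for one method."""
    X = sp.csr_matrix(X)
    rows = [
        _one_repetition(cfg, X, profiles, rep) for rep in range(cfg.repetitions)
    ]
    table = pd.DataFrame(rows)
    bad = ~table[["rank_error_binary", "kpartite_error_graded"]].apply(
        lambda c: c.between(0, 1)
    ).all(axis=None)
    if bad:
        raise AssertionError("metric outside [0, 1]")
    return ExperimentResult(table)


def cutoff_sweep(
    pki_values: np.ndarray,
    cutoffs: Sequence[float],
    cfg: ExperimentConfig,
    X,
) -> dict[float, ExperimentResult]:
    """Re-binarize pK_i values per cutoff and run the stratified protocol."""
    pki_values = np.asarray(pki_values, dtype=float)
    results: dict[float, ExperimentResult] = {}
    for cutoff in cutoffs:
        profiles = (pki_values >= cutoff).astype(int)
        if profiles.sum() == 0:
            raise ValueError(f"cutoff {cutoff} leaves no active compounds")
        sweep_cfg = replace(cfg, protocol="stratified_split")
        results[float(cutoff)] = run_experiment(sweep_cfg, X, profiles)
    return results


def auc(predictions: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with half credit for ties; auc == 1 - rank_error."""
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(predictions, dtype=float)))
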