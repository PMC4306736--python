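"""Comparison methods: per-target SVCs, their linear combination, MC-SVM.

The linear combination (SVM LC) ranks by f(x) = w_combined^T x with
w_combined = sum_i c_i w_i, where each w_i is a soft-margin linear SVC
weight vector for one target and c_i its linear factor (+2 for the
desired activity profile, -1 for undesired targets by default).  The
multi-class SVM treats every rank score as a class and is trained with
the single joint Crammer-Singer optimization; for ranking evaluation
its predicted class values serve as (heavily tied) scores.

SVC and MC-SVM optimization is delegated to liblinear via scikit-learn;
the repo pins the optimization contract (objective within tolerance of
a reference QP solution on small instances), not the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .ranksvm import LinearModel, fingerprints_to_csr


def _as_matrix(fps) -> sp.csr_matrix:
    if sp.issparse(fps):
        return sp.csr_matrix(fps)
    if isinstance(fps, np.ndarray):
        return sp.csr_matrix(fps)
    return fingerprints_to_csr(list(fps))


def fit_svc(fps, labels: Sequence[int], C: float, seed: int = 0,
            tol: float = 1e-9, max_iter: int = 200_000) -> LinearModel:
    """Soft-margin linear SVC (hinge loss, no intercept)."""
    X = _as_matrix(fps)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size != 2:
        raise ValueError("SVC needs exactly two classes present")
    clf = LinearSVC(C=C, loss="hinge", fit_intercept=False, tol=tol,
                    max_iter=max_iter, random_state=seed)
    clf.fit(X, y)
    # liblinear orients w towards the larger label; keep f(x) > 0 <=> positive
    return LinearModel(sp.csr_matrix(clf.coef_), {"C": C, "kind": "svc"})


@dataclass
class CombinationSpec:
    """Models plus their linear factors c_i for w_combined = sum c_i w_i."""

    factors: list[tuple[LinearModel, float]]

    def __post_init__(self):
        if not self.factors:
            raise ValueError("need at least one (model, factor) pair")
        if all(c == 0 for _, c in self.factors):
            raise ValueError("at least one factor must be non-zero")


def combine(spec: CombinationSpec | Sequence[tuple[LinearModel, float]]) -> LinearModel:
    """Elementwise weighted sum of weight vectors (prediction-linear)."""
    if not isinstance(spec, CombinationSpec):
        spec = CombinationSpec(list(spec))
    dim = spec.factors[0][0].dim
    if any(m.dim != dim for m, _ in spec.factors):
        raise ValueError("combined models must share dimension")
    w = sp.csr_matrix((1, dim))
    for model, c in spec.factors:
        w = w + c * model.w
    return LinearModel(sp.csr_matrix(w), {"kind": "svm_lc",
                                          "factors": [c for _, c in spec.factors]})


@dataclass
class MultiClassModel:
    """One weight vector per rank-score class; predicts argmax_k w_k^T x."""

    W: sp.csr_matrix  # (n_classes, dim)
    classes: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = sp.csr_matrix(self.W)
        self.classes = np.asarray(self.classes, dtype=int)
        if self.W.shape[0] != self.classes.size:
            raise ValueError("one weight vector per class required")


def fit_mcsvm(fps, scores: Sequence[int], C: float, seed: int = 0,
              tol: float = 1e-6, max_iter: int = 100_000) -> MultiClassModel:
    """Crammer-Singer multi-class SVM over rank-score classes."""
    X = _as_matrix(fps)
    y = np.asarray(scores, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("MC-SVM needs at least two classes present")
    clf = LinearSVC(C=C, multi_class="crammer_singer", fit_intercept=False,
                    tol=tol, max_iter=max_iter, random_state=seed)
    clf.fit(X, y)
    coef = clf.coef_
    if coef.shape[0] != clf.classes_.size:
        # binary case collapsed to one vector; expand to per-class form
        coef = np.vstack([-coef[0] / 2.0, coef[0] / 2.0])
    return MultiClassModel(sp.csr_matrix(coef), clf.classes_, {"C": C})


def predict_mc(model: MultiClassModel, fps) -> np.ndarray:
    """Predicted class per instance; argmax ties go to the lowest class."""
    X = _as_matrix(fps)
    scores = np.asarray(X @ model.W.T.toarray())
    # classes_ ascending and argmax returns the first maximum
    return model.classes[np.argmax(scores, axis=1)]


def rank_by_mc(model: MultiClassModel, fps) -> np.ndarray:
    """Class values as coarse ranking scores (massive ties expected)."""
    return predict_mc(model, fps).astype(float)
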