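"""Linear ranking SVM with a k-partite, margin-rescaled pairwise loss.

The learner (MT RANK) fits a linear ranking function f(x) = w^T x by
minimizing

    J(w) = 1/2 ||w||^2 + C * L(w)

where, writing P = {(i,j) | s_i > s_j} for the set of orderable pairs
and W = sum_P (s_i - s_j) for the total score-difference weight,

    margin-rescaled:  L(w) = (1/W) sum_P max(0, (s_i - s_j) - w^T(x_i - x_j))
    slack-rescaled:   L(w) = (1/W) sum_P (s_i - s_j) max(0, 1 - w^T(x_i - x_j))

Both are convex upper bounds on the k-partite ranking error

    err_kpart = (1/W) sum_P (s_i - s_j) * loss(i, j)

with loss(i,j) = 1 for a swapped pair, 1/2 for a tied prediction, else
0; a pair of scores further apart therefore costs proportionally more
(margin re-scaling).  With binary scores the k-partite error reduces to
the plain fraction of miss-ranked pairs, which equals 1 - AUC.

L(w) and its subgradient are never computed by enumerating P: one sort
of the l prediction values plus a sweep over the R(R-1)/2 ordered
score-value pairs gives the exact same sums, so evaluation is
O(d*l + R^2*l + l*log l) instead of O(l^2).

The solver is a bundle (cutting-plane) method run in the l-dimensional
kernel space of the training set: each iteration adds the tangent plane
of C*L at the current iterate and re-solves the regularized bundle
subproblem, whose simplex-constrained dual is solved by accelerated
projected gradient; a line search between the incumbent and the QP
iterate closes the primal side of the gap quickly.  The dual value of
the bundle model is a certified lower bound on min J, so terminating
once the gap falls below tol (relative to both the objective and the
initially achievable decrease) guarantees tol-optimality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .fingerprints import SparseFingerprint

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


def fingerprints_to_csr(fps: Sequence[SparseFingerprint]) -> sp.csr_matrix:
    """Stack sparse fingerprints into an (l, dim) CSR matrix."""
    if not fps:
        raise ValueError("no fingerprints")
    dim = fps[0].dim
    if any(fp.dim != dim for fp in fps):
        raise ValueError("fingerprints must share dim")
    indptr = np.zeros(len(fps) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([fp.nnz for fp in fps])
    indices = np.concatenate([fp.indices for fp in fps]) if indptr[-1] else np.empty(0, np.int64)
    data = np.concatenate([fp.values for fp in fps]) if indptr[-1] else np.empty(0)
    return sp.csr_matrix((data, indices, indptr), shape=(len(fps), dim))


@dataclass
class RankDataset:
    """Training instances (sparse features, integer rank score) plus stats."""

    X: sp.csr_matrix
    scores: np.ndarray

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        self.scores = np.asarray(self.scores, dtype=int)
        if self.X.shape[0] != self.scores.size:
            raise ValueError("X rows and scores length differ")
        if self.l < 2:
            raise ValueError("need at least 2 instances")

    @classmethod
    def from_fingerprints(
        cls, fps: Sequence[SparseFingerprint], scores: Sequence[int]
    ) -> "RankDataset":
        return cls(fingerprints_to_csr(fps), np.asarray(scores))

    @property
    def l(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def d(self) -> float:
        """Average number of non-zero features per instance."""
        return self.X.nnz / self.l

    @property
    def R(self) -> int:
        """Number of distinct rank scores."""
        return int(np.unique(self.scores).size)

    def pair_set(self) -> "PairSet":
        return build_pair_set(self.scores)


@dataclass
class PairSet:
    """Ordered pairs (i, j) with s_i > s_j, weighted by s_i - s_j."""

    pairs: np.ndarray  # (n_pairs, 2) int
    weights: np.ndarray  # (n_pairs,) positive int

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())


def build_pair_set(scores: Sequence[int]) -> PairSet:
    scores = np.asarray(scores, dtype=int)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    diff = scores[:, None] - scores[None, :]
    ii, jj = np.nonzero(diff > 0)
    if ii.size == 0:
        logger.warning("all rank scores equal: empty pair set, training impossible")
    return PairSet(np.column_stack([ii, jj]), diff[ii, jj])


@dataclass
class TrainConfig:
    """Solver settings: regularization C, certified gap tolerance, variant."""

    C: float = 1e-4
    tol: float = 1e-5
    max_iter: int = 500
    loss_variant: str = "margin_rescaled"
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.loss_variant not in ("margin_rescaled", "slack_rescaled"):
            raise ValueError(f"unknown loss_variant {self.loss_variant!r}")


@dataclass
class LinearModel:
    """A linear ranking/classification function f(x) = w^T x (no intercept)."""

    w: sp.csr_matrix  # shape (1, dim)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w = sp.csr_matrix(self.w)
        if self.w.shape[0] != 1:
            raise ValueError("w must be a (1, dim) row vector")

    @property
    def dim(self) -> int:
        return self.w.shape[1]

    @classmethod
    def from_dense(cls, w: np.ndarray, config: dict | None = None) -> "LinearModel":
        return cls(sp.csr_matrix(np.asarray(w, dtype=float).reshape(1, -1)),
                   config or {})

    def decision_function(self, X) -> np.ndarray:
        if X.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: {X.shape[1]} vs {self.dim}")
        return np.asarray(X @ self.w.T.toarray()).ravel()


@dataclass
class SolverDiagnostics:
    """Best-so-far objective trace, realized hinge losses, iteration count."""

    objective_trace: list[float]
    gap_trace: list[float]
    hinge_loss: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# metrics


def pair_loss(fi: float, fj: float) -> float:
    """Pairwise 0/0.5/1 loss for an ordered pair (s_i > s_j)."""
    if fi < fj:
        return 1.0
    if fi == fj:
        return 0.5
    return 0.0


def _pairwise_error(predictions, scores, weighted: bool) -> float:
    f = np.asarray(predictions, dtype=float)
    s = np.asarray(scores, dtype=int)
    if f.size != s.size:
        raise ValueError("predictions and scores length differ")
    ps = build_pair_set(s)
    if len(ps) == 0:
        raise ValueError("empty pair set: ranking error undefined")
    fi = f[ps.pairs[:, 0]]
    fj = f[ps.pairs[:, 1]]
    losses = (fi < fj).astype(float) + 0.5 * (fi == fj)
    if weighted:
        return float(np.dot(ps.weights, losses) / ps.total_weight)
    return float(losses.sum() / len(ps))


def rank_error(predictions: Sequence[float], scores: Sequence[int]) -> float:
    """Fraction of miss-ranked pairs (ties count 1/2); 1 - AUC on binary scores."""
    return _pairwise_error(predictions, scores, weighted=False)


def kpartite_error(predictions: Sequence[float], scores: Sequence[int]) -> float:
    """Score-difference-weighted fraction of miss-ranked pairs."""
    return _pairwise_error(predictions, scores, weighted=True)


# ---------------------------------------------------------------------------
# fast loss evaluation


def _group_by_score(scores: np.ndarray) -> list[tuple[int, np.ndarray]]:
    values = np.unique(scores)[::-1]
    return [(int(v), np.nonzero(scores == v)[0]) for v in values]


def weighted_hinge(
    f: np.ndarray, scores: np.ndarray, variant: str = "margin_rescaled"
) -> tuple[float, np.ndarray]:
    """Normalized hinge loss L and its subgradient dL/df by the R^2 sweep.

    Exactly equals the brute-force sum over all pairs in P, but touches
    each score group once per ordered score pair using sorted prediction
    arrays and prefix sums.
    """
    f = np.asarray(f, dtype=float)
    scores = np.asarray(scores, dtype=int)
    groups = _group_by_score(scores)
    if len(groups) < 2:
        raise ValueError("need at least two distinct scores")
    total = 0.0
    grad = np.zeros_like(f)
    W = 0
    sorted_cache = {}
    for v, idx in groups:
        fs = np.sort(f[idx])
        sorted_cache[v] = (fs, np.concatenate([[0.0], np.cumsum(fs)]))
    for hi in range(len(groups)):
        a, A = groups[hi]
        fA_sorted, prefA = sorted_cache[a]
        for lo in range(hi + 1, len(groups)):
            b, B = groups[lo]
            fB_sorted, _ = sorted_cache[b]
            m = a - b
            W += m * A.size * B.size
            if variant == "margin_rescaled":
                thr, weight = float(m), 1.0
            else:
                thr, weight = 1.0, float(m)
            fB = f[B]
            # hinge active for pair (i, j) iff f_i < f_j + thr
            cnt = np.searchsorted(fA_sorted, fB + thr, side="left")
            total += weight * float(np.dot(cnt, fB + thr) - prefA[cnt].sum())
            grad[B] += weight * cnt
            fA = f[A]
            dcnt = B.size - np.searchsorted(fB_sorted, fA - thr, side="right")
            grad[A] -= weight * dcnt
    return total / W, grad / W


def brute_force_hinge(
    f: np.ndarray, scores: np.ndarray, variant: str = "margin_rescaled"
) -> float:
    """O(l^2) pair-expansion reference for the normalized hinge loss."""
    f = np.asarray(f, dtype=float)
    ps = build_pair_set(scores)
    if len(ps) == 0:
        raise ValueError("empty pair set")
    df = f[ps.pairs[:, 0]] - f[ps.pairs[:, 1]]
    m = ps.weights.astype(float)
    if variant == "margin_rescaled":
        hinges = np.maximum(0.0, m - df)
    else:
        hinges = m * np.maximum(0.0, 1.0 - df)
    return float(hinges.sum() / ps.total_weight)


def fast_weighted_loss(model: LinearModel, data: RankDataset,
                       variant: str = "margin_rescaled") -> float:
    """Normalized hinge loss L(w) of a model via the R^2 sweep."""
    f = model.decision_function(data.X)
    value, _ = weighted_hinge(f, data.scores, variant)
    return value


def objective(model: LinearModel, data: RankDataset, cfg: TrainConfig) -> float:
    """Regularized risk J(w) = 1/2 ||w||^2 + C * L(w)."""
    wn = float(model.w.multiply(model.w).sum())
    return 0.5 * wn + cfg.C * fast_weighted_loss(model, data, cfg.loss_variant)


# ---------------------------------------------------------------------------
# bundle solver


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {x >= 0, sum x = 1}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)

def _solve_bundle_qp(G: np.ndarray, b: np.ndarray, lam0: np.ndarray,
                     iters: int = 800, rtol: float = 1e-10) -> tuple[np.ndarray, float]:
    """max_{lam in simplex} b^T lam - 1/2 lam^T G lam by FISTA.

    Returns the (feasible) maximizer and its dual value, which is a
    valid lower bound on the bundle subproblem minimum.
    """
    k = b.size
    if k == 1:
        lam = np.ones(1)
        return lam, float(b[0] - 0.5 * G[0, 0])
    # Lipschitz constant of the gradient: spectral norm by power iteration
    v = np.ones(k) / np.sqrt(k)
    L = float(np.trace(G)) / k
    for _ in range(15):
        Gv = G @ v
        nv = np.linalg.norm(Gv)
        if nv <= 1e-15:
            break
        L = nv
        v = Gv / nv
    L = max(L, 1e-12)
    lam = _project_simplex(lam0.copy())
    y = lam.copy()
    t = 1.0
    prev = -np.inf
    for it in range(iters):
        grad = b - G @ y
        lam_new = _project_simplex(y + grad / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = lam_new + ((t - 1.0) / t_new) * (lam_new - lam)
        lam, t = lam_new, t_new
        if it % 25 == 24:
            val = float(b @ lam - 0.5 * lam @ G @ lam)
            if val - prev <= rtol * max(abs(val), 1.0):
                break
            prev = val
    val = float(b @ lam - 0.5 * lam @ G @ lam)
    return lam, val


def fit(data: RankDataset, cfg: TrainConfig | None = None) -> tuple[LinearModel, SolverDiagnostics]:
    """Train the ranking function; returns (model, diagnostics).

    Certified bundle method: stops once the gap between the best primal
    objective and the bundle lower bound is below ``cfg.tol`` (relative),
    or flags non-convergence after ``cfg.max_iter`` iterations and
    returns the best iterate.
    """
    cfg = cfg or TrainConfig()
    if data.R < 2:
        raise ValueError("degenerate data: need at least two distinct rank scores")
    l = data.l
    K = np.asarray((data.X @ data.X.T).todense(), dtype=float)
    scores = data.scores

    # bundle state, all in the l-dimensional span of the training rows:
    # plane k is  R_emp(w) >= q_k . f(w) + b_k  with f(w) = X w.
    Q: list[np.ndarray] = []  # subgradient coefficient vectors (l,)
    bs: list[float] = []
    KQ = np.zeros((l, 0))
    G = np.zeros((0, 0))
    lam = np.zeros(0)

    def risk_at(fvec: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = weighted_hinge(fvec, scores, cfg.loss_variant)
        return cfg.C * value, cfg.C * grad

    f = np.zeros(l)
    risk, grad = risk_at(f)
    best_obj = risk  # w = 0
    best_coef = np.zeros(l)
    f_best = np.zeros(l)
    obj_trace = [best_obj]
    gap_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # add tangent plane at the latest evaluated point
        Q.append(grad)
        bs.append(risk - float(grad @ f))
        kq = K @ grad
        if KQ.shape[1]:
            cross = KQ.T @ grad
            k = G.shape[0]
            G_new = np.empty((k + 1, k + 1))
            G_new[:k, :k] = G
            G_new[:k, k] = cross
            G_new[k, :k] = cross
            G_new[k, k] = float(grad @ kq)
            G = G_new
        else:
            G = np.array([[float(grad @ kq)]])
        KQ = np.column_stack([KQ, kq])
        lam = np.concatenate([lam * (1 - 1e-3), [1e-3]])

        # bundle subproblem dual: include the implicit zero plane by
        # allowing slack mass on an explicit (0, 0) column
        Gz = np.pad(G, ((0, 1), (0, 1)))
        bz = np.concatenate([np.asarray(bs), [0.0]])
        lam_z, lower = _solve_bundle_qp(Gz, bz, np.concatenate([lam, [0.0]]))
        lam = lam_z[:-1]

        coef_qp = -(np.asarray(Q).T @ lam) if lam.size else np.zeros(l)
        f_qp = K @ coef_qp
        risk, grad = risk_at(f_qp)
        obj_qp = 0.5 * float(coef_qp @ f_qp) + risk
        f = f_qp

        # line search between the incumbent and the QP iterate: the risk is
        # cheap to evaluate, and the improved upper bound closes the gap far
        # faster than the bundle model alone (OCAS-style)
        c_bb = float(best_coef @ f_best)
        c_bq = float(best_coef @ f_qp)
        c_qq = float(coef_qp @ f_qp)
        candidates = [(obj_qp, 1.0, risk)]
        for t in (0.2, 0.4, 0.6, 0.8):
            ft = (1 - t) * f_best + t * f_qp
            rt, _ = risk_at(ft)
            quad = 0.5 * ((1 - t) ** 2 * c_bb + 2 * t * (1 - t) * c_bq
                          + t * t * c_qq)
            candidates.append((quad + rt, t, rt))
        obj_new, t_new, _ = min(candidates, key=lambda c: c[0])
        if obj_new < best_obj:
            best_obj = obj_new
            best_coef = (1 - t_new) * best_coef + t_new * coef_qp
            f_best = (1 - t_new) * f_best + t_new * f_qp
        obj_trace.append(best_obj)
        gap = best_obj - lower
        gap_trace.append(gap)
        # relative both to the objective value (tol-optimality contract) and
        # to the initially achievable decrease, so that small-C problems -
        # where J is nearly flat - are still solved to a meaningful direction
        if it == 1:
            init_gap = max(gap, 1e-15)
        if gap <= cfg.tol * max(min(best_obj, init_gap), 1e-15):
            converged = True
            break
        # prune inactive planes to bound the subproblem size
        if len(bs) > 100:
            keep = [k for k, lk in enumerate(lam) if lk > 1e-12 or k >= len(bs) - 30]
            Q = [Q[k] for k in keep]
            bs = [bs[k] for k in keep]
            KQ = KQ[:, keep]
            G = G[np.ix_(keep, keep)]
            lam = lam[keep]

    if not converged:
        logger.warning("bundle solver: no convergence in %d iterations (gap %.3g)",
                       cfg.max_iter, gap_trace[-1] if gap_trace else float("nan"))
    w = np.asarray(data.X.T @ best_coef).ravel()
    model = LinearModel.from_dense(
        w, {"C": cfg.C, "loss_variant": cfg.loss_variant, "tol": cfg.tol}
    )
    fb = data.X @ w
    hinge, _ = weighted_hinge(np.asarray(fb).ravel(), scores, cfg.loss_variant)
    diag = SolverDiagnostics(obj_trace, gap_trace, hinge, it, converged)
    return model, diag


def predict(model: LinearModel, fps) -> np.ndarray:
    """f(x) = w^T x per instance; accepts fingerprints or a sparse matrix."""
    if sp.issparse(fps) or isinstance(fps, np.ndarray):
        X = fps
    else:
        X = fingerprints_to_csr(list(fps))
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# statsmodels-style surface


class RankSVM:
    """Linear ranking SVM model built from data; ``fit`` returns results.

    Parameters
    ----------
    scores : sequence of int
        Integer rank scores (graded relevance), higher = ranked above.
    X : sparse matrix or sequence of SparseFingerprint
        Feature vectors, one row per compound.
    """

    def __init__(self, scores, X):
        if sp.issparse(X) or isinstance(X, np.ndarray):
            self.data = RankDataset(sp.csr_matrix(X), np.asarray(scores))
        else:
            self.data = RankDataset.from_fingerprints(list(X), scores)

    @classmethod
    def from_dataframe(cls, frame, score_col: str, fps) -> "RankSVM":
        return cls(frame[score_col].to_numpy(), fps)

    def fit(self, C: float = 1e-4, loss_variant: str = "margin_rescaled",
            tol: float = 1e-5, max_iter: int = 500, seed: int = 0) -> "RankSVMResults":
        cfg = TrainConfig(C=C, tol=tol, max_iter=max_iter,
                          loss_variant=loss_variant, seed=seed)
        model, diag = fit(self.data, cfg)
        return RankSVMResults(self, model, diag, cfg)


class RankSVMResults:
    """Fitted ranking function with diagnostics and evaluation helpers."""

    def __init__(self, model_obj: RankSVM, linear_model: LinearModel,
                 diagnostics: SolverDiagnostics, cfg: TrainConfig):
        self.model = model_obj
        self.linear_model = linear_model
        self.diagnostics = diagnostics
        self.config = cfg

    @property
    def params(self) -> sp.csr_matrix:
        return self.linear_model.w

    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    def predict(self, X) -> np.ndarray:
        return predict(self.linear_model, X)

    def training_objective(self) -> float:
        return objective(self.linear_model, self.model.data, self.config)

    def rank_error(self, X=None, scores=None) -> float:
        X = self.model.data.X if X is None else X
        scores = self.model.data.scores if scores is None else scores
        return rank_error(self.predict(X), scores)

    def kpartite_error(self, X=None, scores=None) -> float:
        X = self.model.data.X if X is None else X
        scores = self.model.data.scores if scores is None else scores
        return kpartite_error(self.predict(X), scores)

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Linear ranking SVM (k-partite pairwise hinge)",
            "=" * 46,
            f"instances (l):            {d.l}",
            f"distinct scores (R):      {d.R}",
            f"avg nnz per instance (d): {d.d:.2f}",
            f"loss variant:             {self.config.loss_variant}",
            f"C:                        {self.config.C:g}",
            f"iterations:               {self.diagnostics.iterations}",
            f"converged:                {self.converged}",
            f"objective:                {self.training_objective():.6g}",
            f"hinge loss L(w):          {self.diagnostics.hinge_loss:.6g}",
            f"training kpartite error:  {self.kpartite_error():.6g}",
            f"nonzero weights:          {self.params.nnz}",
        ]
        return "\n".join(lines)
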