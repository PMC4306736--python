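"""Independent reference solvers used to check the in-package optimizers."""

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from multirank.ranksvm import build_pair_set


def qp_oracle_objective(X, scores, C, variant="margin_rescaled"):
    """Optimum of the fully expanded pairwise problem by a generic solver.

    The box-constrained dual of the expanded hinge QP is smooth, so
    L-BFGS-B drives it to high precision; the primal-dual gap certifies
    the recovered solution.
    """
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    ps = build_pair_set(scores)
    D = X[ps.pairs[:, 0]] - X[ps.pairs[:, 1]]
    m = ps.weights.astype(float)
    W = m.sum()
    if variant == "margin_rescaled":
        margins, costs = m, np.full(m.size, C / W)
    else:
        margins, costs = np.ones(m.size), C * m / W

    def neg_dual(alpha):
        v = D.T @ alpha
        return -(margins @ alpha - 0.5 * v @ v), -(margins - D @ v)

    res = minimize(neg_dual, np.zeros(m.size), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, c) for c in costs],
                   options={"maxiter": 50_000, "ftol": 1e-18, "gtol": 1e-14})
    w = D.T @ res.x
    if variant == "margin_rescaled":
        primal = 0.5 * w @ w + (C / W) * np.maximum(0.0, m - D @ w).sum()
    else:
        primal = 0.5 * w @ w + (C / W) * (m * np.maximum(0.0, 1.0 - D @ w)).sum()
    gap = primal - (-res.fun)
    assert gap <= 1e-6 * max(primal, 1.0), "oracle did not converge"
    return primal, w
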