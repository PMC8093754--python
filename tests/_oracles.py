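"""Independent oracles used by the test suite.

These deliberately avoid the package's solver paths: direct constrained
maximization of the transport objective (SLSQP on the primal), the exact
Kantorovich linear program (scipy linprog), and brute-force double
centering.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def direct_transport_maximum(M: np.ndarray, a: np.ndarray, b: np.ndarray,
                             lam: float) -> np.ndarray:
    """Maximize <M,Q> + H(Q)/lam over T(a,b) with a generic NLP solver."""
    n, m = M.shape
    cons = [
        {"type": "eq", "fun": (lambda Q, i=i: Q.reshape(n, m)[i].sum() - a[i])}
        for i in range(n)
    ] + [
        {"type": "eq", "fun": (lambda Q, j=j: Q.reshape(n, m)[:, j].sum() - b[j])}
        for j in range(m - 1)  # last column constraint is redundant
    ]

    def negative_objective(q):
        Q = q.reshape(n, m)
        pos = Q > 1e-300
        H = -np.sum(Q[pos] * np.log(Q[pos]))
        return -(np.sum(M * Q) + H / lam)

    res = optimize.minimize(
        negative_objective, np.outer(a, b).ravel(), constraints=cons,
        bounds=[(1e-12, 1.0)] * (n * m), method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x.reshape(n, m)


def kantorovich_lp(M: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Exact maximum of <M,Q> over T(a,b) by linear programming."""
    n, m = M.shape
    A_eq = np.zeros((n + m, n * m))
    for i in range(n):
        A_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        A_eq[n + j, j::m] = 1.0
    res = optimize.linprog(-M.ravel(), A_eq=A_eq,
                           b_eq=np.concatenate([a, b]), bounds=(0, None))
    assert res.status == 0, res.message
    return float(-res.fun)


def double_center(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=1, keepdims=True)
    return M - M.mean(axis=0, keepdims=True)


def random_instance(rng: np.random.Generator, n: int, m: int,
                    low: float = -2.0, high: float = 2.0):
    """(M, a, b) with strictly positive Dirichlet marginals."""
    M = rng.uniform(low, high, (n, m))
    a = rng.dirichlet(np.ones(n))
    b = rng.dirichlet(np.ones(m))
    # keep marginals strictly positive and well conditioned
    a = (a + 0.01) / (a + 0.01).sum()
    b = (b + 0.01) / (b + 0.01).sum()
    return M, a, b


def fiber_state_key(Y: np.ndarray) -> bytes:
    """Column-major byte key matching the chain's internal occupancy keys."""
    return bytes(int(c) for col in np.asarray(Y, dtype=int).T.tolist() for c in col)
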