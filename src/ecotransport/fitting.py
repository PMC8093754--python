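"""Estimating the utility matrix M from observed couplings.

The fit minimizes, over M,

    sum_l D_KL(P^(l) || Q*_{a^(l), b^(l)}(M))  +  gamma * r(M),

where each observed coupling P^(l) supplies its own marginals as the
transport constraints and r is an L2 (sum of squares) or L1 (sum of
absolute values) penalty.  Because the modeled coupling is the MaxEnt
distribution matching those same marginals, the divergence gradient has
the exact closed form

    d D_KL(P || Q*(M)) / dM = lam * (Q*(M) - P)

in every constraint mode (implicit differentiation of the stationarity
conditions; no unrolling of Sinkhorn is needed).  With both marginals
fixed M is identifiable only up to additive row/column offsets (the
gauge freedom), which the regularizer resolves; the reported matrix is
double-centered with the removed offsets returned alongside.

``grid_search_lambda`` covers the converse task: M known, the trade-off
lam selected by minimizing D_KL(P || Q*(M, lam)) over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .netio import Coupling, ValidationError
from .transport import (
    TransportProblem,
    UtilityMatrix,
    kl_divergence,
    solve,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "regularizer_value",
    "regularizer_gradient",
    "fit_objective_and_gradient",
    "fit_utility",
    "grid_search_lambda",
]


@dataclass
class FitConfig:
    """Hyper-parameters for utility-matrix estimation.

    lam is fixed at 1 by default: scaling M and 1/lam together leaves
    the optimal coupling unchanged, so lam is a redundant degree of
    freedom during fitting.
    """

    gamma: float = 1e-4
    regularizer: str = "l2"
    lam: float = 1.0
    mode: str = "both-fixed"
    tol_inner: float = 1e-8
    max_iter_inner: int = 5000
    tol_outer: float = 1e-7
    max_outer_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if self.tol_inner <= 0 or self.tol_outer <= 0:
            raise ValidationError("tolerances must be > 0")
        reg = self.regularizer.lower()
        if reg not in ("l2", "l1"):
            raise ValidationError("regularizer must be 'l2' or 'l1'")
        self.regularizer = reg


@dataclass
class FitResult:
    """Fitted utility matrix plus diagnostics.

    ``M_hat`` is the canonical (double-centered) representative;
    ``row_offsets``/``col_offsets`` are what was subtracted, so the raw
    optimizer iterate is ``M_hat.matrix + row_offsets[:, None] +
    col_offsets[None, :]`` on permitted cells.
    """

    M_hat: UtilityMatrix
    final_objective: float
    per_network_kl: list[float]
    converged: bool
    n_outer_iterations: int
    row_offsets: np.ndarray | None = None
    col_offsets: np.ndarray | None = None
    modeled: list[Coupling] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)


def regularizer_value(M: UtilityMatrix | np.ndarray, kind: str = "l2") -> float:
    """L2 -> sum M_ij^2; L1 -> sum |M_ij| (forbidden cells excluded)."""
    if isinstance(M, UtilityMatrix):
        vals = M.matrix[~M.forbidden]
    else:
        vals = np.asarray(M, dtype=float).ravel()
    kind = kind.lower()
    if kind == "l2":
        return float(np.sum(vals ** 2))
    if kind == "l1":
        return float(np.sum(np.abs(vals)))
    raise ValidationError(f"unknown regularizer kind {kind!r}")


def regularizer_gradient(vals: np.ndarray, kind: str) -> np.ndarray:
    if kind == "l2":
        return 2.0 * vals
    return np.sign(vals)  # L1 subgradient (0 at 0)


def _check_shapes(observed: list[Coupling]) -> tuple[int, int]:
    if not observed:
        raise ValidationError("need at least one observed coupling")
    shape = observed[0].shape
    for k, P in enumerate(observed):
        if P.shape != shape:
            raise ValidationError(
                f"coupling {k} has shape {P.shape}, expected {shape}"
            )
    return shape


def _solve_for(M: UtilityMatrix, P: Coupling, config: FitConfig):
    mode = config.mode
    a = P.row_marginal if mode in ("both-fixed", "row-fixed") else None
    b = P.col_marginal if mode in ("both-fixed", "col-fixed") else None
    prob = TransportProblem(M, lam=config.lam, mode=mode, a=a, b=b)
    return solve(prob, tol=config.tol_inner, max_iter=config.max_iter_inner)


def fit_objective_and_gradient(M_values: np.ndarray, observed: list[Coupling],
                               config: FitConfig,
                               forbidden: np.ndarray | None = None):
    """Objective sum_l KL_l + gamma r(M) and its exact gradient w.r.t. M.

    ``M_values`` holds the permitted entries (full matrix with zeros at
    forbidden cells).  Returns (value, gradient, per_network_kl).
    """
    shape = _check_shapes(observed)
    M = UtilityMatrix(M_values.reshape(shape).copy(), forbidden=forbidden)
    permitted = ~M.forbidden
    grad = np.zeros(shape)
    kls = []
    for P in observed:
        sol = _solve_for(M, P, config)
        kl = kl_divergence(P, sol.coupling)
        kls.append(kl)
        grad += config.lam * (sol.coupling.matrix - P.matrix)
    value = float(np.sum(kls)) + config.gamma * regularizer_value(M, config.regularizer)
    grad += config.gamma * regularizer_gradient(
        np.where(permitted, M.matrix, 0.0), config.regularizer
    )
    grad[~permitted] = 0.0
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite fit objective ({value}) at ||M|| = "
            f"{np.linalg.norm(M.matrix):.3g}"
        )
    return value, grad, kls


def _double_center(M: np.ndarray):
    """Remove row and column means (canonical gauge representative)."""
    row = M.mean(axis=1, keepdims=True)
    centered = M - row
    col = centered.mean(axis=0, keepdims=True)
    centered = centered - col
    return centered, row.ravel(), col.ravel()


def fit_utility(observed: list[Coupling] | Coupling,
                config: FitConfig | None = None,
                forbidden: np.ndarray | None = None) -> FitResult:
    """Fit a single utility matrix to one or several observed couplings.

    Quasi-Newton (L-BFGS) minimization on the flattened matrix, starting
    from M = 0 (the neutral model, which is also the regularizer's
    minimum).  Deterministic.  Cells under ``forbidden`` carry no
    parameter and stay masked in the result.
    """
    if isinstance(observed, Coupling):
        observed = [observed]
    config = config or FitConfig()
    shape = _check_shapes(observed)
    if forbidden is not None and np.asarray(forbidden).shape != shape:
        raise ValidationError("forbidden mask shape does not match couplings")

    x0 = np.zeros(shape).ravel()

    def fun(x):
        value, grad, _ = fit_objective_and_gradient(x, observed, config, forbidden)
        return value, grad.ravel()

    trace: list[float] = [fun(x0)[0]]

    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        callback=lambda xk: trace.append(fun(xk)[0]),
        options={"gtol": config.tol_outer, "ftol": 0.0,
                 "maxiter": config.max_outer_iter},
    )
    M_raw = res.x.reshape(shape)

    # canonical representative: full double-centering is gauge-free only
    # with both marginals fixed; otherwise only a global shift is free.
    if config.mode == "both-fixed":
        centered, row_off, col_off = _double_center(M_raw)
    else:
        mean = M_raw.mean()
        centered = M_raw - mean
        row_off = np.full(shape[0], mean)
        col_off = np.zeros(shape[1])
    M_hat = UtilityMatrix(centered, forbidden=forbidden)
    # report objective/KL at the returned representative so the numbers
    # in the result are mutually consistent
    value, _, kls = fit_objective_and_gradient(
        M_hat.matrix.ravel(), observed, config, forbidden
    )
    modeled = [_solve_for(M_hat, P, config).coupling for P in observed]
    return FitResult(
        M_hat=M_hat,
        final_objective=value,
        per_network_kl=[float(k) for k in kls],
        converged=bool(res.success) or res.status == 0,
        n_outer_iterations=int(res.nit),
        row_offsets=row_off,
        col_offsets=col_off,
        modeled=modeled,
        objective_trace=trace,
    )


def grid_search_lambda(P: Coupling, M: UtilityMatrix,
                       grid, mode: str = "both-fixed",
                       tol: float = 1e-9, max_iter: int = 100_000):
    """Select lam minimizing D_KL(P || Q*(M, lam)) over a grid.

    Returns (lam_best, kl_curve) with the full curve as a list aligned
    with ``grid``; ties break toward the smaller lam.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValidationError("lambda grid must be non-empty")
    curve = []
    for lam in grid:
        a = P.row_marginal if mode in ("both-fixed", "row-fixed") else None
        b = P.col_marginal if mode in ("both-fixed", "col-fixed") else None
        sol = solve(TransportProblem(M, lam=lam, mode=mode, a=a, b=b),
                    tol=tol, max_iter=max_iter)
        curve.append(kl_divergence(P, sol.coupling))
    order = sorted(range(len(grid)), key=lambda k: (curve[k], grid[k]))
    return grid[order[0]], curve
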