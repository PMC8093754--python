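"""Entropy-regularized optimal transportation between two species levels.

The modeled coupling Q maximizes

    <M, Q> + (1/lam) * H(Q)

over a constraint set determined by ``mode``:

=============  ==========================  ===========================
mode           constraints                 solution form
=============  ==========================  ===========================
both-fixed     row sums a, column sums b   Q_ij = alpha_i beta_j e^(lam M_ij)
row-fixed      row sums a                  Q_ij = a_i softmax_j(lam M_i.)
col-fixed      column sums b               Q_ij = b_j softmax_i(lam M_.j)
free           total sum 1                 Q_ij = softmax(lam M)_ij
=============  ==========================  ===========================

M is the pairwise utility matrix, lam >= 0 the utility/entropy trade-off
(an inverse temperature): lam -> 0 gives the neutral model Q = a b^T,
lam -> infinity the Kantorovich linear program.  Only the both-fixed
mode needs iterations (log-domain Sinkhorn scaling); the other three
have closed forms.  Forbidden links are a boolean mask standing for
M_ij = -infinity and yield exactly zero coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netio import Coupling, ValidationError

__all__ = [
    "UtilityMatrix",
    "TransportProblem",
    "TransportSolution",
    "FeasibilityError",
    "MODES",
    "average_utility",
    "entropy",
    "objective",
    "kl_divergence",
    "solve",
]

MODES = ("both-fixed", "row-fixed", "col-fixed", "free")

#: default L-infinity marginal tolerance for Sinkhorn
DEFAULT_TOL = 1e-9
#: default iteration cap for Sinkhorn
DEFAULT_MAX_ITER = 100_000
#: stall detection window/threshold for infeasible forbidden-link patterns
_STALL_WINDOW = 100
_STALL_RELATIVE = 1e-12


class FeasibilityError(RuntimeError):
    """No coupling with the required marginals exists on the permitted support."""


@dataclass
class UtilityMatrix:
    """Pairwise utility (preference/efficiency) matrix M.

    ``forbidden`` marks species pairs that cannot interact (utility
    -infinity, coupling exactly zero).  Entries of ``matrix`` at
    forbidden cells are ignored.  A matrix containing ``-inf`` entries
    may be passed directly; those cells are absorbed into the mask.
    """

    matrix: np.ndarray
    forbidden: np.ndarray | None = None
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("utility matrix must be two-dimensional")
        mask = np.zeros(self.matrix.shape, dtype=bool) if self.forbidden is None \
            else np.asarray(self.forbidden, dtype=bool).copy()
        if mask.shape != self.matrix.shape:
            raise ValidationError("forbidden mask shape does not match matrix")
        mask |= np.isneginf(self.matrix)
        if not np.all(np.isfinite(self.matrix[~mask])):
            raise ValidationError("utility matrix has non-finite permitted entries")
        self.forbidden = mask
        self.matrix = np.where(mask, 0.0, self.matrix)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def effective(self) -> np.ndarray:
        """M with forbidden cells as -inf (for direct use in exponents)."""
        return np.where(self.forbidden, -np.inf, self.matrix)


@dataclass
class TransportProblem:
    """One optimal-transport instance: utility, trade-off and constraints."""

    utility: UtilityMatrix
    lam: float = 1.0
    mode: str = "both-fixed"
    a: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        n, m = self.utility.shape
        needs_a = self.mode in ("both-fixed", "row-fixed")
        needs_b = self.mode in ("both-fixed", "col-fixed")
        if needs_a != (self.a is not None):
            raise ValidationError(f"mode {self.mode!r}: row marginal a "
                                  + ("required" if needs_a else "must be absent"))
        if needs_b != (self.b is not None):
            raise ValidationError(f"mode {self.mode!r}: column marginal b "
                                  + ("required" if needs_b else "must be absent"))
        for name, vec, size in (("a", self.a, n), ("b", self.b, m)):
            if vec is None:
                continue
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (size,):
                raise ValidationError(f"marginal {name} has length {vec.shape}, "
                                      f"expected {size}")
            if (vec < 0).any():
                raise ValidationError(f"marginal {name} has negative entries")
            if not np.isclose(vec.sum(), 1.0, atol=1e-10):
                raise ValidationError(f"marginal {name} sums to {vec.sum()}, expected 1")
            setattr(self, name, vec)


@dataclass
class TransportSolution:
    """Solved coupling with its scaling factors and summary functionals."""

    coupling: Coupling
    row_scalings: np.ndarray | None = None
    col_scalings: np.ndarray | None = None
    free_normalizer: float | None = None
    attained_utility: float = 0.0
    entropy: float = 0.0
    iterations: int = 0
    converged: bool = True
    marginal_error: float = 0.0
    problem: TransportProblem | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# functionals


def _coupling_array(Q) -> np.ndarray:
    return Q.matrix if isinstance(Q, Coupling) else np.asarray(Q, dtype=float)


def average_utility(M: UtilityMatrix | np.ndarray, Q) -> float:
    """<M, Q> over permitted cells; forbidden cells contribute zero."""
    Qm = _coupling_array(Q)
    if isinstance(M, UtilityMatrix):
        if M.shape != Qm.shape:
            raise ValidationError(f"shape mismatch: M {M.shape} vs Q {Qm.shape}")
        return float(np.sum(np.where(M.forbidden, 0.0, M.matrix * Qm)))
    M = np.asarray(M, dtype=float)
    if M.shape != Qm.shape:
        raise ValidationError(f"shape mismatch: M {M.shape} vs Q {Qm.shape}")
    return float(np.sum(M * Qm))


def entropy(Q) -> float:
    """Shannon entropy -sum Q log Q (natural log, 0 log 0 := 0)."""
    Qm = _coupling_array(Q)
    if (Qm < 0).any():
        raise ValidationError("entropy of a matrix with negative entries")
    pos = Qm > 0
    return float(-np.sum(Qm[pos] * np.log(Qm[pos])))


def objective(M: UtilityMatrix | np.ndarray, Q, lam: float) -> float:
    """The regularized objective <M,Q> + (1/lam) H(Q); requires lam > 0."""
    if lam <= 0:
        raise ValidationError("objective requires lam > 0 (lam = 0 is the neutral "
                              "branch of solve)")
    return average_utility(M, Q) + entropy(Q) / lam


def kl_divergence(P, Q) -> float:
    """Kullback-Leibler divergence D_KL(P || Q) = sum P log(P/Q) >= 0.

    Cells with P_ij = 0 contribute zero; P_ij > 0 with Q_ij = 0 gives
    +infinity.
    """
    Pm, Qm = _coupling_array(P), _coupling_array(Q)
    if Pm.shape != Qm.shape:
        raise ValidationError(f"shape mismatch: P {Pm.shape} vs Q {Qm.shape}")
    pos = Pm > 0
    if np.any(Qm[pos] == 0):
        return float("inf")
    return float(np.sum(Pm[pos] * np.log(Pm[pos] / Qm[pos])))


# ---------------------------------------------------------------------------
# solver


def _logsumexp(arr: np.ndarray, axis=None):
    """log-sum-exp that tolerates all--inf slices (returns -inf there)."""
    mx = np.max(arr, axis=axis, keepdims=True)
    mx_safe = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(arr - mx_safe), axis=axis, keepdims=True)) + mx_safe
    out = np.where(np.isfinite(mx), out, -np.inf)
    return out if axis is None else np.squeeze(out, axis=axis)


def _softmax_from_log(logits: np.ndarray):
    z = float(_logsumexp(logits.ravel(), axis=0))
    return np.exp(logits - z), z


def _sinkhorn_log(logK: np.ndarray, a: np.ndarray, b: np.ndarray,
                  tol: float, max_iter: int):
    """Log-domain Sinkhorn on strictly positive marginals.

    logK = lam * M with -inf at forbidden cells.  Returns
    (logQ, f, g, iterations, converged, marginal_error).
    """
    log_a, log_b = np.log(a), np.log(b)
    f = np.zeros_like(a)  # log row scalings
    g = np.zeros_like(b)  # log col scalings
    err_hist: list[float] = []
    err = np.inf
    it = 0
    forbidden_present = np.isneginf(logK).any()
    for it in range(1, max_iter + 1):
        f = log_a - _logsumexp(logK + g[None, :], axis=1)
        g = log_b - _logsumexp(logK + f[:, None], axis=0)
        logQ = logK + f[:, None] + g[None, :]
        Q = np.exp(logQ)
        err = max(np.abs(Q.sum(axis=1) - a).max(), np.abs(Q.sum(axis=0) - b).max())
        if err < tol:
            return logQ, f, g, it, True, err
        if forbidden_present:
            err_hist.append(err)
            if len(err_hist) > _STALL_WINDOW:
                old = err_hist[-_STALL_WINDOW - 1]
                if old > 0 and (old - err) / old < _STALL_RELATIVE and err > 1e-6:
                    raise FeasibilityError(
                        "Sinkhorn stalled at marginal error "
                        f"{err:.3g}: the forbidden-link pattern admits no "
                        "coupling with the required marginals"
                    )
    logQ = logK + f[:, None] + g[None, :]
    return logQ, f, g, it, False, err


def solve(problem: TransportProblem, tol: float = DEFAULT_TOL,
          max_iter: int = DEFAULT_MAX_ITER) -> TransportSolution:
    """Solve one entropy-regularized transport problem.

    Species with zero marginal abundance are removed before solving and
    re-inserted as zero rows/columns.  lam = 0 (or a constant utility
    matrix) short-circuits to the analytic neutral solution.
    """
    M = problem.utility
    n, m = M.shape
    lam = problem.lam
    mode = problem.mode
    logM = M.effective()

    permitted = ~M.forbidden
    constant_M = np.all(M.forbidden) or (
        permitted.all() and np.ptp(M.matrix) == 0.0
    )

    # --- analytic neutral branch -------------------------------------------
    if lam == 0.0 or constant_M:
        if mode == "both-fixed":
            Q = np.outer(problem.a, problem.b)
        elif mode == "row-fixed":
            Q = np.repeat(problem.a[:, None] / m, m, axis=1)
        elif mode == "col-fixed":
            Q = np.repeat(problem.b[None, :] / n, n, axis=0)
        else:
            Q = np.full((n, m), 1.0 / (n * m))
        return TransportSolution(
            coupling=Coupling(Q, kind="modeled"),
            attained_utility=average_utility(M, Q),
            entropy=entropy(Q),
            iterations=0,
            converged=True,
            marginal_error=0.0,
            problem=problem,
        )

    # --- closed-form modes -------------------------------------------------
    if mode == "free":
        Q, z = _softmax_from_log(lam * logM)
        return TransportSolution(
            coupling=Coupling(Q, kind="modeled"),
            free_normalizer=float(np.exp(-z)),
            attained_utility=average_utility(M, Q),
            entropy=entropy(Q),
            iterations=0, converged=True, marginal_error=0.0,
            problem=problem,
        )

    if mode in ("row-fixed", "col-fixed"):
        axis = 1 if mode == "row-fixed" else 0
        marg = problem.a if mode == "row-fixed" else problem.b
        lse = _logsumexp(lam * logM, axis=axis)
        if np.any(np.isneginf(lse) & (marg > 0)):
            raise FeasibilityError(
                "a species with positive abundance has all links forbidden"
            )
        with np.errstate(divide="ignore"):
            log_marg = np.log(marg)
        shift = (log_marg - lse)
        logQ = lam * logM + (shift[:, None] if axis == 1 else shift[None, :])
        Q = np.where(np.isneginf(logQ), 0.0, np.exp(logQ))
        scal = np.exp(shift)
        return TransportSolution(
            coupling=Coupling(Q, kind="modeled"),
            row_scalings=scal if mode == "row-fixed" else None,
            col_scalings=scal if mode == "col-fixed" else None,
            attained_utility=average_utility(M, Q),
            entropy=entropy(Q),
            iterations=0, converged=True, marginal_error=0.0,
            problem=problem,
        )

    # --- both-fixed: Sinkhorn ----------------------------------------------
    a, b = problem.a, problem.b
    rows = np.flatnonzero(a > 0)
    cols = np.flatnonzero(b > 0)
    a_sub, b_sub = a[rows], b[cols]
    logK = lam * logM[np.ix_(rows, cols)]
    if np.any(np.isneginf(_logsumexp(logK, axis=1))) or \
            np.any(np.isneginf(_logsumexp(logK, axis=0))):
        raise FeasibilityError(
            "a species with positive abundance has all links forbidden"
        )
    logQ_sub, f, g, it, conv, err = _sinkhorn_log(logK, a_sub, b_sub, tol, max_iter)
    Q = np.zeros((n, m))
    Q[np.ix_(rows, cols)] = np.where(np.isneginf(logQ_sub), 0.0, np.exp(logQ_sub))
    alpha = np.zeros(n)
    beta = np.zeros(m)
    with np.errstate(over="ignore"):  # harmlessly inf at extreme lam
        alpha[rows] = np.exp(f)
        beta[cols] = np.exp(g)
    # renormalize exactly to a simplex element (residual <= tol)
    total = Q.sum()
    Qc = Coupling(Q / total, kind="modeled")
    return TransportSolution(
        coupling=Qc,
        row_scalings=alpha,
        col_scalings=beta,
        attained_utility=average_utility(M, Qc.matrix),
        entropy=entropy(Qc.matrix),
        iterations=it,
        converged=conv,
        marginal_error=float(err),
        problem=problem,
    )
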