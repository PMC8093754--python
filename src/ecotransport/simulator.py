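"""Bottom-up swap dynamics on integer interaction matrices.

A margin-preserving Markov chain demonstrates that the optimal-transport
coupling emerges from purely local decisions.  One step:

1. draw two bottom species (columns) j1, j2 with replacement,
   proportional to their interaction totals;
2. for each, draw a top species (row) proportional to that column's
   entries, giving cells (i1, j1) and (i2, j2);
3. propose moving one interaction from (i1, j1) and (i2, j2) to
   (i1, j2) and (i2, j1) — row and column totals are conserved by
   construction;
4. accept with probability min(1, exp(lam * dM)) where
   dM = M[i1,j2] + M[i2,j1] - M[i1,j1] - M[i2,j2].

Because cells are proposed proportional to their counts, the chain is
reversible with respect to

    pi(Y)  ∝  exp(lam * <Y, M>) / prod_ij Y_ij!

on the fiber of integer matrices with the initial margins — the
margin-conditioned multinomial ensemble exponentially tilted by utility.
Its expectation approaches L * Q*(M, lam) (the both-fixed transport
solution) as the interaction count L grows, which is exactly the
emergence property the chain is meant to exhibit.  ``enumerate_fiber``
and ``stationary_distribution`` compute this law exactly on small
instances for validation; the flat-base measure ∝ exp(lam <Y, M>)
(``base="flat"``) is also available for comparison and differs
systematically from the chain's law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .netio import InteractionCounts, ValidationError
from .transport import UtilityMatrix

__all__ = [
    "SwapChainConfig",
    "SwapChainResult",
    "propose_swap",
    "accept_swap",
    "run_chain",
    "enumerate_fiber",
    "stationary_distribution",
]

#: finite stand-in utility for forbidden links inside the chain, keeping
#: it ergodic while making forbidden configurations very unlikely
FORBIDDEN_UTILITY = -10.0


@dataclass
class SwapChainConfig:
    """Chain length, trade-off, seeding and sampling schedule."""

    n_steps: int = 100_000
    lam: float = 1.0
    seed: int = 0
    burn_in: int = 0
    sample_every: int = 1
    keep_samples: bool = False
    track_states: bool = False

    def __post_init__(self) -> None:
        if not self.n_steps > self.burn_in >= 0:
            raise ValidationError("need n_steps > burn_in >= 0")
        if self.sample_every < 1:
            raise ValidationError("sample_every must be >= 1")


@dataclass
class SwapChainResult:
    mean_coupling: np.ndarray
    mean_utility: float
    utility_sd: float
    acceptance_rate: float
    n_samples: int
    samples: list[np.ndarray] | None = None
    state_counts: dict[bytes, int] | None = field(default=None, repr=False)


def _column_draw(counts_col, total, u):
    """Index into one column proportional to its entries (u in [0,1))."""
    target = u * total
    acc = 0.0
    for i, c in enumerate(counts_col):
        acc += c
        if target < acc:
            return i
    return len(counts_col) - 1  # guard against roundoff at u ~ 1


def propose_swap(Y: InteractionCounts | np.ndarray, rng: np.random.Generator):
    """Draw one candidate swap (i1, j1, i2, j2) from the current state.

    Columns are drawn with replacement proportional to column totals,
    rows within each drawn column proportional to that column's entries.
    The proposed move decrements (i1, j1) and (i2, j2) and increments
    (i1, j2) and (i2, j1).  Degenerate draws (i1 = i2 or j1 = j2) are
    valid proposals leaving the state unchanged.
    """
    mat = Y.matrix if isinstance(Y, InteractionCounts) else np.asarray(Y)
    col_tot = mat.sum(axis=0)
    L = col_tot.sum()
    if L <= 0:
        raise ValidationError("cannot propose a swap on an empty matrix")
    cum = np.cumsum(col_tot) / L
    j1 = int(np.searchsorted(cum, rng.random(), side="right"))
    j2 = int(np.searchsorted(cum, rng.random(), side="right"))
    i1 = _column_draw(mat[:, j1], col_tot[j1], rng.random())
    i2 = _column_draw(mat[:, j2], col_tot[j2], rng.random())
    return i1, j1, i2, j2


def accept_swap(delta_M: float, lam: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(lam * delta_M))."""
    if delta_M > 0:
        return True
    return bool(rng.random() < np.exp(lam * delta_M))


def run_chain(Y0: InteractionCounts, M: UtilityMatrix,
              config: SwapChainConfig) -> SwapChainResult:
    """Run the swap chain and report ensemble averages.

    Post-burn-in states are sampled every ``sample_every`` proposals.
    The mean coupling is the average of Y/L over samples; the mean
    utility is the matching average of <M, Y/L>.  Forbidden cells of M
    take the finite utility ``FORBIDDEN_UTILITY``.  Bit-reproducible
    given (seed, config).
    """
    if Y0.shape != M.shape:
        raise ValidationError(f"shape mismatch: Y {Y0.shape} vs M {M.shape}")
    Mf = np.where(M.forbidden, FORBIDDEN_UTILITY, M.matrix)
    n, m = Y0.shape
    L = Y0.total_count
    if L <= 0:
        raise ValidationError("initial matrix has no interactions")
    lam = config.lam
    rng = np.random.Generator(np.random.PCG64(config.seed))

    # column-major python ints: column totals are invariant under swaps,
    # so the column-selection cumulative is fixed for the whole chain.
    cols = [[int(Y0.matrix[i, j]) for i in range(n)] for j in range(m)]
    col_tot = [float(sum(c)) for c in cols]
    cum = np.cumsum(col_tot) / L
    Mrows = [[float(Mf[i, j]) for j in range(m)] for i in range(n)]

    row_tot0 = Y0.matrix.sum(axis=1).copy()
    col_tot0 = Y0.matrix.sum(axis=0).copy()

    U = float(sum(cols[j][i] * Mrows[i][j] for j in range(m) for i in range(n)))

    accepted = 0
    acc_counts = np.zeros((n, m))
    util_sum = 0.0   # accumulated relative to the first sampled utility
    util_sq = 0.0    # (avoids cancellation when the utility is constant)
    util_ref = None
    n_samples = 0
    samples: list[np.ndarray] | None = [] if config.keep_samples else None
    state_counts: dict[bytes, int] | None = {} if config.track_states else None

    def snapshot() -> np.ndarray:
        return np.array(cols, dtype=float).T

    block = 65536
    drawn = 0
    uni = rng.random((0, 5))
    for step in range(1, config.n_steps + 1):
        if drawn >= uni.shape[0]:
            uni = rng.random((block, 5))
            drawn = 0
        u = uni[drawn]
        drawn += 1
        j1 = int(np.searchsorted(cum, u[0], side="right"))
        j2 = int(np.searchsorted(cum, u[1], side="right"))
        i1 = _column_draw(cols[j1], col_tot[j1], u[2])
        i2 = _column_draw(cols[j2], col_tot[j2], u[3])
        if j1 == j2 or i1 == i2:
            accepted += 1  # degenerate proposal: dM = 0, state unchanged
        else:
            dM = Mrows[i1][j2] + Mrows[i2][j1] - Mrows[i1][j1] - Mrows[i2][j2]
            if dM > 0 or u[4] < np.exp(lam * dM):
                cols[j1][i1] -= 1
                cols[j2][i2] -= 1
                cols[j2][i1] += 1
                cols[j1][i2] += 1
                U += dM
                accepted += 1
        if step > config.burn_in:
            if state_counts is not None:
                key = bytes(c for col in cols for c in col)
                state_counts[key] = state_counts.get(key, 0) + 1
            if (step - config.burn_in - 1) % config.sample_every == 0:
                Ynow = snapshot()
                if not (np.array_equal(Ynow.sum(axis=1), row_tot0)
                        and np.array_equal(Ynow.sum(axis=0), col_tot0)):
                    raise AssertionError("margin conservation violated")
                acc_counts += Ynow
                u_now = U / L
                if util_ref is None:
                    util_ref = u_now
                d = u_now - util_ref
                util_sum += d
                util_sq += d * d
                n_samples += 1
                if samples is not None:
                    samples.append(Ynow.astype(int))

    mean_coupling = acc_counts / (n_samples * L)
    mean_d = util_sum / n_samples
    var = max(util_sq / n_samples - mean_d ** 2, 0.0)
    return SwapChainResult(
        mean_coupling=mean_coupling,
        mean_utility=util_ref + mean_d,
        utility_sd=float(np.sqrt(var)),
        acceptance_rate=accepted / config.n_steps,
        n_samples=n_samples,
        samples=samples,
        state_counts=state_counts,
    )


# ---------------------------------------------------------------------------
# exact enumeration on small instances


def enumerate_fiber(row_sums, col_sums) -> list[np.ndarray]:
    """All non-negative integer matrices with the given margins.

    Exponential in size; intended for validation on tiny instances
    (L up to ~10 on 3x3).
    """
    row_sums = [int(r) for r in row_sums]
    col_sums = [int(c) for c in col_sums]
    if sum(row_sums) != sum(col_sums):
        raise ValidationError("row and column sums disagree")
    n, m = len(row_sums), len(col_sums)
    out: list[np.ndarray] = []

    def rows(idx: int, remaining_cols: list[int], acc: list[list[int]]):
        if idx == n:
            if all(c == 0 for c in remaining_cols):
                out.append(np.array(acc, dtype=float))
            return
        target = row_sums[idx]

        def cells(j: int, left: int, row: list[int]):
            if j == m - 1:
                if left <= remaining_cols[j]:
                    full = row + [left]
                    rem = [remaining_cols[k] - full[k] for k in range(m)]
                    rows(idx + 1, rem, acc + [full])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                cells(j + 1, left - v, row + [v])

        cells(0, target, [])

    rows(0, list(col_sums), [])
    return out


def stationary_distribution(fiber: list[np.ndarray], M: UtilityMatrix,
                            lam: float, base: str = "multinomial") -> np.ndarray:
    """Exact law on an enumerated fiber.

    ``base="multinomial"`` gives the chain's stationary distribution
    pi(Y) ∝ exp(lam <Y, M>) / prod Y_ij!; ``base="flat"`` gives the
    counting-measure Gibbs weights ∝ exp(lam <Y, M>).
    """
    Mf = np.where(M.forbidden, FORBIDDEN_UTILITY, M.matrix)
    logw = np.array([
        lam * float(np.sum(Y * Mf))
        - (float(np.sum(gammaln(Y + 1))) if base == "multinomial" else 0.0)
        for Y in fiber
    ])
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()
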