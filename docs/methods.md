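# Methods

## Model

Two species levels interact: a top level *A* with *n* species and
relative abundances **a**, and a bottom level *B* with *m* species and
abundances **b** (both on the probability simplex). A coupling *Q* is a
joint distribution over pairs; observed couplings are normalized count
matrices *P = Y/L* with *L* the total interaction count. (Some sources
refer to this *L* as "connectance"; it is a total count, not the
links/(n·m) density, and the package names it `total_count`.)

The modeled coupling maximizes `⟨M,Q⟩ + (1/λ)H(Q)` subject to marginal
constraints. Four regimes are supported:

| mode       | constraints              | solution form                  |
|------------|--------------------------|--------------------------------|
| both-fixed | row sums a, col sums b   | `αᵢβⱼ exp(λMᵢⱼ)` (Sinkhorn)    |
| row-fixed  | row sums a               | per-row softmax × aᵢ           |
| col-fixed  | col sums b               | per-column softmax × bⱼ        |
| free       | total sum 1              | global softmax of λM           |

For λ > 0 and both marginals fixed the problem is strictly convex with
a unique optimum. Two invariances matter throughout: adding a constant
to *M* never changes *Q\**, and scaling *M* by *s* while replacing λ by
λ/s changes nothing either. Hence λ can be fixed to 1 whenever *M* is
itself being estimated. With both marginals fixed the invariance is
stronger — adding any `uᵢ + vⱼ` to *M* leaves *Q\** unchanged (gauge
freedom) — which is what makes the fitting problem ill-posed without
regularization.

## Solver

The both-fixed solver is Sinkhorn matrix scaling run entirely in the
log domain (log-sum-exp updates on the dual potentials `f = log α`,
`g = log β`). This keeps λM safe far beyond the ±700 overflow range of
naive scaling and represents forbidden links as exact −∞ entries that
produce exact zeros in *Q*. Choices:

- **Convergence**: L∞ deviation of both empirical marginals below
  `tol` (default 1e-9), iteration cap 10⁵. On non-convergence the
  solution is returned with `converged=False` and the residual in
  `marginal_error`.
- **λ = 0 / constant M**: returned analytically as `a bᵀ` (and the
  corresponding uniform forms in the relaxed modes), not iterated.
- **Zero abundances**: species with zero marginal are removed before
  solving and re-inserted as zero rows/columns, keeping the scaling
  vectors strictly positive.
- **Infeasible forbidden-link patterns** (no coupling with the required
  marginals exists on the permitted support) are detected by a stalled
  marginal residual — relative improvement below 1e-12 over a
  100-iteration window while the error is still above 1e-6 — and raise
  a `FeasibilityError`. A fully forbidden row or column with positive
  abundance is rejected upfront.
- Natural logarithms throughout (entropy, KL divergence, softmax
  algebra).
- At extreme λ (~10³) convergence can need tens of thousands of
  iterations when the optimum sits near a vertex of the polytope;
  the returned utilities are nonetheless accurate to ~1e-9 of the
  linear-programming optimum on small instances.

The KL divergence is implemented in the standard orientation,
`D_KL(P‖Q) = Σ P log(P/Q) ≥ 0`, with `0·log 0 := 0` and +∞ when *P*
puts mass where *Q* has none; minimizing it is what the fit does.

## Fitting M

The fit minimizes `Σ_l D_KL(P⁽ˡ⁾ ‖ Q*_{a⁽ˡ⁾,b⁽ˡ⁾}(M)) + γ·r(M)` where
each observed coupling contributes its own marginals as constraints and
`r` is `‖M‖₂²` (default) or `‖M‖₁`. Because *Q\*(M)* is the
maximum-entropy distribution matching exactly those marginals, implicit
differentiation of the stationarity conditions collapses the gradient
to the closed form

```
∂/∂M  D_KL(P ‖ Q*(M)) = λ (Q*(M) − P),
```

valid in all four constraint modes. This is the classical
exponential-family likelihood gradient; no differentiation through the
Sinkhorn iterations is required, and the tests verify it against
central finite differences to ~1e-7 relative error.

Choices:

- λ fixed to 1 during fitting (the scale invariance above makes it
  redundant); λ re-enters only in `grid_search_lambda`, where *M* is
  known and the single scalar is selected by scanning
  `D_KL(P ‖ Q*(M, λ))` over a user grid, ties broken toward smaller λ.
- Initialization at M = 0 (the neutral model and the regularizer's
  minimizer); the optimizer is L-BFGS with gradient-norm stopping
  (default 1e-7, cap 500 outer iterations). Deterministic.
- Inner Sinkhorn budget during fitting: tolerance 1e-8, 5·10³
  iterations per evaluation.
- The reported `M_hat` is double-centered (zero row and column means)
  as the canonical representative of the gauge class, with the removed
  offsets returned alongside; entries near zero then read directly as
  "neutral", positive as "more than expected by chance", negative as
  "less". In relaxed modes only a global constant is gauge-free, so
  only the mean is removed. The reported objective and per-network KL
  values are recomputed at the returned representative so they are
  mutually consistent.
- Forbidden cells carry no parameter and are excluded from the
  penalty; they are structural zeros, not estimable preferences.
- No pseudo-counts are added to *Y*: regularization, not smoothing, is
  what resolves the ill-posedness (pseudo-counts cannot, because of the
  additive invariance of *M*).
- The L1 penalty uses the sign subgradient inside L-BFGS; this is
  adequate for the small, smooth-dominated problems targeted here but
  will not produce exact zeros the way a proximal method would — a
  known limitation.

## Swap-chain simulation

The simulator shows the transport solution emerging bottom-up. A state
is an integer matrix *Y* with fixed row and column totals. One step
draws two columns with replacement proportional to their totals, one
row within each column proportional to that column's entries — so a
cell is selected with probability `Y_ij/L` — and proposes moving one
interaction from cells (i₁,j₁), (i₂,j₂) to (i₁,j₂), (i₂,j₁), preserving
all margins by construction. The proposal is accepted with probability
`min(1, exp(λΔM))`, `ΔM = M_{i₁j₂} + M_{i₂j₁} − M_{i₁j₁} − M_{i₂j₂}`.
Degenerate draws (equal rows or columns) count as accepted proposals
that change nothing.

Because the proposal probability of a swap is proportional to
`Y_{i₁j₁}Y_{i₂j₂}`, detailed balance holds with respect to

```
π(Y) ∝ exp(λ ⟨Y, M⟩) / Πᵢⱼ Yᵢⱼ! ,
```

the margin-conditioned multinomial ensemble exponentially tilted by
utility — *not* the flat counting-measure Gibbs law
`∝ exp(λ⟨Y,M⟩)`. The distinction is systematic and measurable: on an
enumerable 3×3 fiber the chain's occupancy matches π to total-variation
≲ 0.005 at 10⁶ steps while differing from the flat-base law by TV ≈
0.2 (both numbers are recomputed by the acceptance script and reported
side by side). The multinomial base is also what makes the ensemble
mean of *Y/L* converge to the Sinkhorn coupling as *L* grows, since π
is the conditional law of independent multinomial sampling with cell
weights `∝ exp(λM)` given the margins — precisely the emergence
property the simulation demonstrates. At λ = 0, π reduces to the
margin-conditioned neutral (multivariate hypergeometric-type) ensemble,
which the tests check by enumeration.

Forbidden links inside the chain use a finite utility of −10 rather
than −∞, keeping the chain ergodic while making forbidden
configurations vanishingly rare. The chain is bit-reproducible given
(seed, config); `enumerate_fiber` performs exhaustive enumeration of
the margin-fixed fiber for validation and is exponential in size —
intended for L ≤ ~10 on 3×3.

## Synthetic communities

The generator emulates sparse bipartite count data with heterogeneous
marginals and trait-driven preference structure:

- **Trait matching**: bottom species have one scalar trait; top
  species respond through a Gaussian density `M_ij = N(t_j | μ_i,
  σ_i²)`. σ is the niche breadth: doubling it halves the attainable
  peak utility, so specialists out-earn generalists at their preferred
  partner. Defaults: 5 bottom traits evenly spaced on [0,1]; 4 top
  species with locations spread over [0,1] and alternating breadths
  0.12 / 0.30 (mixed specialists and generalists).
- **Abundances**: symmetric Dirichlet(1) draws (uniform on the
  simplex), seed-controlled.
- **Counts**: multinomial with *L* trials and cell probabilities *Q*.
- **Scenarios**: extinction of a bottom species (drop + renormalize
  **b**), an invading top species (append a Gaussian response row +
  renormalize **a**), and abundance replacement. Each returns a
  ready-to-solve problem. The "fully adapted" regime is modeled with
  `mode="free"` (global softmax).

What the generator does **not** emulate: phylogenetic or spatial
structure, observation effort bias, multi-trait niches, or the species
richness of real archived networks. Tests passing on these synthetic
communities therefore establish correctness of the algorithms and the
qualitative regime structure (utility-driven vs neutral vs free), not
predictive performance on field data.

## Problem sizes and tolerances in the validation suite

The test suite and acceptance script use: 200 random instances with
n, m ≤ 8 and λ ∈ {0.1, 1, 10} for marginal feasibility (1e-8); 20
random 3×3 instances against a generic SLSQP maximizer (1e-5) and 5
against the LP limit at λ = 10³ (1e-3); 50 instances for the
invariances (1e-8); a 3×3, L = 6 fiber with 10⁶ chain steps for
stationarity (TV < 0.02) and a 5×5, L = 200, 10⁵-swap, 10-repeat setup
for utility emergence (within one ensemble SD); a 5×4 recovery fit at
γ = 10⁻⁶ (KL < 10⁻⁴, centered correlation > 0.99); and a 21-point λ
grid at 0.05 resolution for trade-off recovery. These sizes keep the
full validation run around a minute on one CPU while leaving each
check's outcome far from its threshold.

## Known limitations

- Single-problem (looped) solving only; no batched/parallel Sinkhorn.
- No unbalanced transport, Wasserstein distances or barycenters.
- No cross-validation for γ; it is a user-set flag.
- No uncertainty quantification on the fitted *M*.
- The bilinear trait regression `M = X_A W X_Bᵀ` is out of scope; *M*
  is fitted entry-wise.
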