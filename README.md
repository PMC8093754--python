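# ecotransport

Entropy-regularized optimal transportation for bipartite species
interaction networks: pollination, seed dispersal, host–parasite and
similar two-level systems.

## The problem

Field observations of who-interacts-with-whom give an integer count
matrix *Y* (rows: top-level species *A*, e.g. pollinators; columns:
bottom-level species *B*, e.g. plants). Normalizing by the total count
*L* gives the observed coupling *P = Y/L*, a joint distribution over
species pairs whose marginals **a** and **b** are the relative
abundances of the two levels. Two forces shape *P*: species *prefer*
partners (trait matching, efficiency), and species meet *at random* in
proportion to abundance (neutral effects). This package models the
interplay of the two as an optimal-transport problem.

Given a pairwise utility matrix *M* (how much species *i* gains from
interacting with species *j*) and a trade-off parameter λ ≥ 0, the
modeled coupling is

```
Q* = argmax_{Q ∈ T(a,b)}  ⟨M, Q⟩ + (1/λ) · H(Q)
```

where `T(a,b)` is the transportation polytope (non-negative matrices
with row sums **a** and column sums **b**), `⟨M, Q⟩ = Σᵢⱼ MᵢⱼQᵢⱼ` is the
average utility and `H(Q) = −Σᵢⱼ Qᵢⱼ log Qᵢⱼ` the entropy. λ acts as an
inverse temperature: λ → 0 gives the neutral model `Q = a bᵀ`; λ → ∞
gives the Kantorovich linear program. The solution has the form
`Qᵢⱼ = αᵢ βⱼ exp(λMᵢⱼ)` and is found by log-domain Sinkhorn scaling.
Relaxing one or both marginal constraints gives three further regimes
(row-fixed, column-fixed, free), each with a closed-form softmax
solution; they model systems whose abundances have had time to adapt.

The package provides:

- **transport** — the solver in all four constraint regimes, with
  forbidden links (`Mᵢⱼ = −∞`, exactly zero coupling), plus the
  functionals ⟨M,Q⟩, H(Q) and D_KL(P‖Q);
- **fitting** — estimation of *M* from one or several observed
  couplings by regularized KL minimization (L2 or L1 penalty,
  quasi-Newton with an exact gradient), and grid search for λ when *M*
  is known;
- **simulator** — a margin-preserving stochastic swap chain showing
  that the transport coupling emerges bottom-up from local
  utility-driven decisions;
- **synthetic** — Gaussian trait-matching communities, abundance
  draws, multinomial count sampling and ecosystem-edit scenarios
  (extinction, invasion, abundance shifts);
- **netio** — labeled CSV/TSV input and output for all objects;
- a `ecotransport` command-line tool wrapping all of the above.

## Worked example

A small trait-matching community: five plants with traits evenly spaced
on [0, 1], four animals with Gaussian responses (two specialists with
niche breadth σ = 0.1, two generalists with σ = 0.3), uneven animal
abundances and uniform plant abundances.

```python
import numpy as np
import ecotransport as et

model = et.TraitModel(bottom_traits=[0.0, 0.25, 0.5, 0.75, 1.0],
                      top_locations=[0.1, 0.4, 0.6, 0.9],
                      top_scales=[0.1, 0.3, 0.1, 0.3])
M = et.trait_matching_utility(model)
a = np.array([0.4, 0.3, 0.2, 0.1])   # animal abundances
b = np.full(5, 0.2)                  # plant abundances

sol = et.solve(et.TransportProblem(M, lam=1.0, mode="both-fixed", a=a, b=b))
print(np.round(sol.coupling.matrix, 3))
print(f"U = {sol.attained_utility:.3f}, H = {sol.entropy:.3f}, "
      f"iterations = {sol.iterations}")
```

prints

```
[[0.169 0.104 0.023 0.042 0.063]
 [0.022 0.078 0.068 0.069 0.063]
 [0.006 0.011 0.1   0.059 0.024]
 [0.003 0.007 0.009 0.03  0.05 ]]
U = 1.212, H = 2.673, iterations = 17
```

Each row sums to that animal's abundance and each column to the plant's;
within those constraints the coupling concentrates on trait-matched
pairs (the first specialist on the low-trait plants, the second on the
mid-trait plant). The attained average utility U = 1.212 compares with
0.739 for the neutral coupling `a bᵀ` at the cost of lowering entropy
from 2.889 to 2.673; `et.kl_divergence(sol.coupling, neutral.coupling)`
= 0.216 quantifies how far preferences push the system from neutrality.

The same computation from the shell:

```sh
ecotransport generate --seed 3 --out-prefix sim
ecotransport solve --utility sim_M.csv --row-abund sim_a.csv \
    --col-abund sim_b.csv --lam 1.0 --out Q.csv --report run.json
ecotransport fit --networks sim_Y.csv --gamma 1e-4 --out M_hat.csv
ecotransport simulate --counts sim_Y.csv --utility sim_M.csv \
    --lam 1.0 --steps 100000 --seed 1 --out mean.csv
```

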