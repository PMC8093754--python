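"""Synthetic ecosystems: trait-matching utilities, abundances, counts.

The generator mirrors a standard trait-matching setup for bipartite
networks: every bottom species carries one scalar trait t_j, every top
species responds to traits through a Gaussian curve with location mu_i
(its preferred trait) and scale sigma_i (its niche breadth), so

    M_ij = N(t_j | mu_i, sigma_i^2)  (normal pdf).

Specialists (small sigma) attain a higher peak utility than generalists
(large sigma) — a design choice of this simulation family, not a
property of the transport model.  Defaults: five bottom species with
traits evenly spaced on [0, 1] and four top species with locations
spread over [0, 1] and mixed niche breadths.  Abundance fixtures are
symmetric Dirichlet(1) draws; observed counts are multinomial samples
from a coupling.

``scenario`` edits a base ecosystem (extinction of a bottom species,
arrival of an invading top species, abundance shifts) into a
ready-to-solve transport problem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .netio import Coupling, InteractionCounts, ValidationError
from .transport import TransportProblem, UtilityMatrix

__all__ = [
    "TraitModel",
    "Ecosystem",
    "trait_matching_utility",
    "sample_counts",
    "random_abundances",
    "default_trait_model",
    "default_ecosystem",
    "scenario",
]


@dataclass
class TraitModel:
    """Scalar bottom traits plus per-top-species Gaussian responses."""

    bottom_traits: np.ndarray
    top_locations: np.ndarray
    top_scales: np.ndarray

    def __post_init__(self) -> None:
        self.bottom_traits = np.asarray(self.bottom_traits, dtype=float)
        self.top_locations = np.asarray(self.top_locations, dtype=float)
        self.top_scales = np.asarray(self.top_scales, dtype=float)
        if self.top_locations.shape != self.top_scales.shape:
            raise ValidationError("top locations and scales differ in length")
        if (self.top_scales <= 0).any():
            raise ValidationError("top scales (niche breadths) must be > 0")

    @property
    def n_top(self) -> int:
        return len(self.top_locations)

    @property
    def n_bottom(self) -> int:
        return len(self.bottom_traits)


@dataclass
class Ecosystem:
    """A trait model with abundance vectors: the unit other modules consume."""

    traits: TraitModel
    a: np.ndarray  # top-level relative abundances
    b: np.ndarray  # bottom-level relative abundances

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (self.traits.n_top,):
            raise ValidationError("abundance a does not match the number of top species")
        if self.b.shape != (self.traits.n_bottom,):
            raise ValidationError("abundance b does not match the number of bottom species")

    def utility(self) -> UtilityMatrix:
        return trait_matching_utility(self.traits)

    def problem(self, lam: float = 1.0, mode: str = "both-fixed") -> TransportProblem:
        a = self.a if mode in ("both-fixed", "row-fixed") else None
        b = self.b if mode in ("both-fixed", "col-fixed") else None
        return TransportProblem(self.utility(), lam=lam, mode=mode, a=a, b=b)


def trait_matching_utility(model: TraitModel) -> UtilityMatrix:
    """M_ij = normal pdf of trait t_j under (mu_i, sigma_i); no forbidden cells."""
    t = model.bottom_traits[None, :]
    mu = model.top_locations[:, None]
    sig = model.top_scales[:, None]
    M = np.exp(-0.5 * ((t - mu) / sig) ** 2) / (sig * np.sqrt(2.0 * np.pi))
    return UtilityMatrix(M)


def sample_counts(Q: Coupling, L: int, seed: int) -> InteractionCounts:
    """Multinomial sample of L interactions with cell probabilities Q."""
    if L <= 0:
        raise ValidationError("L must be > 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    n, m = Q.shape
    flat = rng.multinomial(L, Q.matrix.ravel() / Q.matrix.sum())
    labels_r = Q.row_labels or [f"A{i+1}" for i in range(n)]
    labels_c = Q.col_labels or [f"B{j+1}" for j in range(m)]
    return InteractionCounts(flat.reshape(n, m), labels_r, labels_c)


def random_abundances(k: int, seed: int) -> np.ndarray:
    """Symmetric Dirichlet(1) abundance draw (uniform on the simplex)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.dirichlet(np.ones(k))


def default_trait_model(n_top: int = 4, n_bottom: int = 5) -> TraitModel:
    """The study's default community: traits on [0,1], mixed specificity."""
    t = np.linspace(0.0, 1.0, n_bottom)
    mu = np.linspace(0.05, 0.95, n_top)
    # alternate specialists and generalists
    scales = np.where(np.arange(n_top) % 2 == 0, 0.12, 0.30)
    return TraitModel(t, mu, scales)


def default_ecosystem(seed: int = 0, n_top: int = 4, n_bottom: int = 5) -> Ecosystem:
    traits = default_trait_model(n_top, n_bottom)
    return Ecosystem(
        traits,
        a=random_abundances(n_top, seed),
        b=random_abundances(n_bottom, seed + 1),
    )


def _renormalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s <= 0:
        raise ValidationError("abundance vector renormalizes to zero")
    return v / s


def scenario(base: Ecosystem, edit: dict, lam: float = 1.0,
             mode: str = "both-fixed") -> TransportProblem:
    """Apply one ecosystem edit and return the transport problem to solve.

    ``edit`` is one of::

        {"kind": "extinction", "species": j}          # drop bottom species j
        {"kind": "invader", "mu": ..., "sigma": ...,
         "abundance": ...}                            # append a top species
        {"kind": "abundance-shift", "a": ... and/or "b": ...}
    """
    kind = edit.get("kind")
    if kind == "extinction":
        j = int(edit["species"])
        if not 0 <= j < base.traits.n_bottom:
            raise ValidationError(f"no bottom species with index {j}")
        if base.traits.n_bottom <= 1:
            raise ValidationError("extinction would empty the bottom level")
        keep = [k for k in range(base.traits.n_bottom) if k != j]
        traits = replace(base.traits, bottom_traits=base.traits.bottom_traits[keep])
        eco = Ecosystem(traits, base.a.copy(), _renormalize(base.b[keep]))
    elif kind == "invader":
        abund = float(edit["abundance"])
        if abund < 0:
            raise ValidationError("invader abundance must be >= 0")
        traits = replace(
            base.traits,
            top_locations=np.append(base.traits.top_locations, float(edit["mu"])),
            top_scales=np.append(base.traits.top_scales, float(edit["sigma"])),
        )
        a = _renormalize(np.append(base.a, abund))
        eco = Ecosystem(traits, a, base.b.copy())
    elif kind == "abundance-shift":
        a = np.asarray(edit.get("a", base.a), dtype=float)
        b = np.asarray(edit.get("b", base.b), dtype=float)
        eco = Ecosystem(base.traits, _renormalize(a), _renormalize(b))
    else:
        raise ValidationError(f"unknown scenario kind {kind!r}")
    return eco.problem(lam=lam, mode=mode)
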