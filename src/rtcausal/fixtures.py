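"""Seeded random populations and property-targeted fixture populations.

Everything downstream of the type algebra is testable against populations
generated here; no external data is ever needed.  Random populations draw a
sparse support of response types and a Dirichlet(1) mass over it — the
uniform distribution on the probability simplex — plus uniform per-type
confounder probabilities.  Targeted fixtures either construct a population
with the desired independence structure exactly (product-form strata,
carefully coupled potential-outcome pairs) or rejection-sample random
populations until the target bias gap is certified by the `conditions`
module.  Certification failure raises; a fixture never silently misses its
target property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import (
    check_condition,
    confounding_gap,
    selection_gap,
)
from .measures import causal_rr
from .population import DesignSpec, PopulationSpec
from .response_types import RestrictionSet, enumerate_types

#: minimum ratio-scale departure certified for "biased" fixtures; keeps the
#: shipped fixtures far from the boundary where float noise could flip them
BIAS_GAP_MIN = 0.05

TARGET_PROPERTIES = (
    "none",
    "et_dt",
    "e_dt_only",
    "full_exch_only",
    "cond_exch_only",
    "confounded",
    "selection_biased",
    "effect_modified",
    "rr_worked_example",
)


class FixtureError(RuntimeError):
    """A fixture recipe could not be satisfied or failed certification."""


@dataclass(frozen=True)
class FixtureRecipe:
    name: str
    seed: int = 0
    restrictions: RestrictionSet = field(default_factory=RestrictionSet)
    target_property: str = "none"
    n_support: int = 12
    n_total: float = 100_000.0

    def __post_init__(self):
        if self.target_property not in TARGET_PROPERTIES:
            raise FixtureError(
                f"unknown target property {self.target_property!r}; "
                f"expected one of {TARGET_PROPERTIES}"
            )


def random_population(
    seed: int | np.random.Generator,
    restrictions: RestrictionSet | None = None,
    n_support: int = 12,
    n_total: float = 100_000.0,
) -> PopulationSpec:
    """A sparse random population over the admissible types.

    Support types are drawn without replacement; the mass over the support
    is Dirichlet(1); confounder probabilities are i.i.d. uniform.
    Deterministic given the seed.
    """
    if n_support < 1:
        raise FixtureError(f"n_support must be >= 1, got {n_support}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    allowed = enumerate_types(restrictions)
    if not allowed:
        raise FixtureError("restrictions leave no admissible types")
    n_support = min(n_support, len(allowed))
    idx = rng.choice(len(allowed), size=n_support, replace=False)
    support = [allowed[i] for i in sorted(idx)]
    mass_values = rng.dirichlet(np.ones(n_support))
    # fsum-exact renormalization so validation at tolerance 1e-9 never trips
    mass_values = mass_values / mass_values.sum()
    pc_values = rng.uniform(size=n_support)
    mass = {tuple(t): float(p) for t, p in zip(support, mass_values)}
    cgt = {tuple(t): float(p) for t, p in zip(support, pc_values)}
    return PopulationSpec(n_total, mass, cgt)


# ---------------------------------------------------------------------------
# Exact constructions for the exchangeability strictness exhibits
# ---------------------------------------------------------------------------

def _product_form_population(seed: int, n_total: float) -> PopulationSpec:
    """E-type ⊥ (D-type, S-type) within each confounder stratum, so the
    strongest condition (type independence given C) holds by construction."""
    rng = np.random.default_rng(seed)
    e_types = [1, 2, 3, 4]
    ds_pairs = [(j, k) for j in (1, 4, 6, 16) for k in (1, 16)]
    strata = {}
    for c in (1, 0):
        p_i = rng.dirichlet(np.ones(len(e_types)))
        p_jk = rng.dirichlet(np.ones(len(ds_pairs)))
        strata[c] = {
            (i, j, k): float(pi * pjk)
            for i, pi in zip(e_types, p_i)
            for (j, k), pjk in zip(ds_pairs, p_jk)
        }
    return PopulationSpec.from_conditional(n_total, 0.5, strata[1], strata[0])


def _e_dt_only_population(n_total: float) -> PopulationSpec:
    """E ⊥ D-type | C holds while E-type ⊥ D-type | C fails.

    Within the C=1 stratum the D-type depends on the E type, but the two E
    types mapping to the same observed exposure carry opposite dependence,
    so the dependence is invisible to observed E; the C=0 stratum is fully
    independent.
    """
    a = {}  # conditional law given C=1 over (i, j, k); k=1 throughout
    for i, p_j1 in ((1, 0.9), (2, 0.1), (3, 0.5), (4, 0.5)):
        a[(i, 1, 1)] = 0.25 * p_j1
        a[(i, 16, 1)] = 0.25 * (1.0 - p_j1)
    b = {}
    for i in (1, 2, 3, 4):
        b[(i, 1, 1)] = 0.125
        b[(i, 16, 1)] = 0.125
    return PopulationSpec.from_conditional(n_total, 0.5, a, b)


def _full_exch_only_population(n_total: float) -> PopulationSpec:
    """Full conditional exchangeability holds while E ⊥ D-type | C fails.

    Exposure is correlated with the half of the D-type bit vector that is
    counterfactual in the current stratum: within C=1 the pair (D_11, D_10)
    is independent of E but (D_01, D_00) is exposure-determined, and
    symmetrically within C=0.
    """
    # E types 1 (always exposed) and 4 (never exposed): E = [i == 1] in both strata
    a = {  # given C=1: (D11, D10) uniform on {(1,1),(0,0)}, (D01, D00) set by E
        (1, 1, 1): 0.25, (1, 11, 1): 0.25,   # E=1: D-types (1,1,1,1), (0,1,0,1)
        (4, 6, 1): 0.25, (4, 16, 1): 0.25,   # E=0: D-types (1,0,1,0), (0,0,0,0)
    }
    b = {  # given C=0: (D01, D00) uniform, (D11, D10) set by E
        (1, 1, 1): 0.25, (1, 6, 1): 0.25,
        (4, 11, 1): 0.25, (4, 16, 1): 0.25,
    }
    return PopulationSpec.from_conditional(n_total, 0.5, a, b)


def _cond_exch_only_population(n_total: float) -> PopulationSpec:
    """Conditional exchangeability holds arm by arm while the joint
    (full) version fails.

    Given either stratum, each single potential outcome is Bernoulli(1/2)
    independent of exposure, but the exposed carry perfectly concordant
    potential-outcome pairs and the unexposed perfectly discordant ones.
    """
    law = {
        (1, 1, 1): 0.25, (1, 16, 1): 0.25,   # E=1: pairs (1,1) and (0,0)
        (4, 4, 1): 0.25, (4, 13, 1): 0.25,   # E=0: pairs (1,0) and (0,1)
    }
    return PopulationSpec.from_conditional(n_total, 0.5, law, dict(law))


def _worked_example_population(n_total: float) -> PopulationSpec:
    """Single-type population: always-exposed, confounder-caused disease,
    selection following disease under exposure; confounder prevalence 0.3."""
    return PopulationSpec(n_total, {(1, 6, 4): 1.0}, {(1, 6, 4): 0.3})


# ---------------------------------------------------------------------------
# Rejection-sampled bias fixtures
# ---------------------------------------------------------------------------

_MAX_ATTEMPTS = 500


def _rejection_sample(recipe: FixtureRecipe, predicate) -> PopulationSpec:
    seeds = np.random.SeedSequence(recipe.seed).spawn(_MAX_ATTEMPTS)
    for ss in seeds:
        pop = random_population(
            np.random.default_rng(ss), recipe.restrictions, recipe.n_support, recipe.n_total
        )
        if predicate(pop):
            return pop
    raise FixtureError(
        f"no population satisfying {recipe.target_property!r} found in "
        f"{_MAX_ATTEMPTS} attempts (seed {recipe.seed}, n_support {recipe.n_support})"
    )


def _is_confounded(pop: PopulationSpec) -> bool:
    gap = confounding_gap(pop)
    return gap.determinate and abs(gap.ratio - 1.0) > BIAS_GAP_MIN


def _is_selection_biased(pop: PopulationSpec) -> bool:
    gap = selection_gap(pop, "causal", DesignSpec("rct_marginal", 0.5))
    return gap.determinate and abs(gap.ratio - 1.0) > BIAS_GAP_MIN


def _is_effect_modified(pop: PopulationSpec) -> bool:
    rr1, rr0 = causal_rr(pop, stratum=1), causal_rr(pop, stratum=0)
    if not (rr1.defined and rr0.defined):
        return False
    return abs(rr1.value / rr0.value - 1.0) > BIAS_GAP_MIN


# ---------------------------------------------------------------------------
# Recipe dispatch and certification
# ---------------------------------------------------------------------------

def _certify(pop: PopulationSpec, prop: str) -> None:
    def holds(variant):
        return check_condition(pop, variant).holds

    ok = True
    if prop == "et_dt":
        ok = holds("et_dt_given_c") is True
    elif prop == "e_dt_only":
        ok = holds("et_dt_given_c") is False and holds("e_dt_given_c") is True
    elif prop == "full_exch_only":
        ok = holds("e_dt_given_c") is False and holds("full_cond_exch") is True
    elif prop == "cond_exch_only":
        ok = holds("full_cond_exch") is False and holds("cond_exch") is True
    elif prop == "confounded":
        ok = _is_confounded(pop)
    elif prop == "selection_biased":
        ok = _is_selection_biased(pop)
    elif prop == "effect_modified":
        ok = _is_effect_modified(pop)
    if not ok:
        raise FixtureError(f"generated population failed certification for {prop!r}")


def make_fixture(recipe: FixtureRecipe) -> PopulationSpec:
    """Build and certify a population with the recipe's target property."""
    prop = recipe.target_property
    if prop == "none":
        pop = random_population(
            recipe.seed, recipe.restrictions, recipe.n_support, recipe.n_total
        )
    elif prop == "et_dt":
        pop = _product_form_population(recipe.seed, recipe.n_total)
    elif prop == "e_dt_only":
        pop = _e_dt_only_population(recipe.n_total)
    elif prop == "full_exch_only":
        pop = _full_exch_only_population(recipe.n_total)
    elif prop == "cond_exch_only":
        pop = _cond_exch_only_population(recipe.n_total)
    elif prop == "confounded":
        pop = _rejection_sample(recipe, _is_confounded)
    elif prop == "selection_biased":
        pop = _rejection_sample(recipe, _is_selection_biased)
    elif prop == "effect_modified":
        pop = _rejection_sample(recipe, _is_effect_modified)
    elif prop == "rr_worked_example":
        pop = _worked_example_population(recipe.n_total)
    else:  # pragma: no cover - guarded by FixtureRecipe
        raise FixtureError(prop)
    _certify(pop, prop)
    return pop


def named_fixture(name: str, seed: int = 0) -> PopulationSpec:
    """Shorthand: build the fixture whose target property is ``name``."""
    return make_fixture(FixtureRecipe(name=name, seed=seed, target_property=name))
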