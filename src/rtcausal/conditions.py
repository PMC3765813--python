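"""Exchangeability auditing, the implication chain, positivity, and bias gaps.

Four nested independence conditions license causal inference from
observational data, ordered from strongest to weakest:

1. ``et_dt_given_c``   — E-type ⊥ D-type | C (response-type independence),
2. ``e_dt_given_c``    — E ⊥ D-type | C,
3. ``full_cond_exch``  — E ⊥ (D_{e=1}, D_{e=0}) | C (full conditional
   exchangeability),
4. ``cond_exch``       — E ⊥ D_e | C for each e (conditional
   exchangeability, the textbook "no unmeasured confounding").

Each implies the next; the weakest already suffices for the standardized
associational risk ratio to equal the causal risk ratio.  All checks run on
the exact analytic joint law of the finite discrete population — never on
samples — so the default tolerance is essentially float round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .measures import RiskRatioValue, assoc_rr, causal_rr, std_rr
from .population import (
    DesignSpec,
    OBSERVATIONAL,
    PopulationSpec,
    cell_frequencies,
    obs_cell_frequencies,
)
from .response_types import potential

#: the condition variants, strongest first
CONDITION_VARIANTS = ("et_dt_given_c", "e_dt_given_c", "full_cond_exch", "cond_exch")

#: absolute tolerance on probability products for independence
INDEPENDENCE_TOL = 1e-12


@dataclass(frozen=True)
class ConditionReport:
    """Verdict of one independence condition on one population."""

    variant: str
    holds: Optional[bool]  # None = indeterminate (zero-mass conditioning event)
    max_deviation: float
    reason: Optional[str] = None


def _independence_deviation(atoms: Iterable[tuple[object, object, float]]) -> float:
    """Max |P(a, b) - P(a) P(b)| over the joint law given as weighted atoms."""
    joint: dict[tuple[object, object], float] = {}
    pa: dict[object, float] = {}
    pb: dict[object, float] = {}
    total = 0.0
    for a, b, w in atoms:
        joint[(a, b)] = joint.get((a, b), 0.0) + w
        pa[a] = pa.get(a, 0.0) + w
        pb[b] = pb.get(b, 0.0) + w
        total += w
    if total <= 0:
        return math.nan
    dev = 0.0
    for a in pa:
        for b in pb:
            dev = max(dev, abs(joint.get((a, b), 0.0) / total - (pa[a] / total) * (pb[b] / total)))
    return dev


def _stratum_atoms(pop: PopulationSpec, design: DesignSpec, variant: str, c: int):
    """Weighted atoms ``(A, B, w)`` of the pair tested by ``variant`` within
    confounder stratum ``c``.  Under a trial design the observed exposure is
    exogenous Bernoulli; observationally it follows consistency (E = E_C)."""
    for t, cv, p in pop.joint():
        if cv != c:
            continue
        i, j, _k = t
        if variant == "et_dt_given_c":
            b_vals = [(j, 1.0)]
            a_vals = [(i, 1.0)]
        else:
            if variant == "e_dt_given_c":
                b = j
            elif variant == "full_cond_exch":
                b = (potential("D", j, c, 1), potential("D", j, c, 0))
            else:
                raise AssertionError(variant)
            b_vals = [(b, 1.0)]
            if design.mode == "observational":
                a_vals = [(potential("E", i, c), 1.0)]
            else:
                p_e = design.p_e_given_c(c)
                a_vals = [(1, p_e), (0, 1.0 - p_e)]
        for a, wa in a_vals:
            for b, wb in b_vals:
                w = p * wa * wb
                if w > 0:
                    yield a, b, w


def check_condition(
    pop: PopulationSpec,
    variant: str,
    tol: float = INDEPENDENCE_TOL,
    design: DesignSpec = OBSERVATIONAL,
) -> ConditionReport:
    """Test one exchangeability condition on the exact joint law.

    ``cond_exch`` tests ``E ⊥ D_e | C`` separately for each intervention arm
    ``e`` and reports the worst deviation; ``full_cond_exch`` tests the joint
    potential-outcome pair.  Returns an indeterminate report when either
    confounder stratum has zero mass, since a conditional independence with
    a zero-mass conditioning event has no truth value.
    """
    if variant not in CONDITION_VARIANTS:
        raise ValueError(f"unknown condition variant {variant!r}; expected one of {CONDITION_VARIANTS}")
    p_c = pop.p_c
    if p_c <= 0 or p_c >= 1:
        return ConditionReport(
            variant, None, math.nan, reason=f"confounder stratum with zero mass (P(C)={p_c})"
        )
    max_dev = 0.0
    for c in (0, 1):
        if variant == "cond_exch":
            # one independence statement per intervention arm
            for e in (1, 0):
                max_dev = max(
                    max_dev, _independence_deviation(_cond_exch_atoms(pop, design, c, e))
                )
        else:
            max_dev = max(
                max_dev, _independence_deviation(_stratum_atoms(pop, design, variant, c))
            )
    return ConditionReport(variant, max_dev <= tol, max_dev)


def _cond_exch_atoms(pop: PopulationSpec, design: DesignSpec, c: int, e: int):
    for t, cv, p in pop.joint():
        if cv != c:
            continue
        i, j, _k = t
        d_e = potential("D", j, c, e)
        if design.mode == "observational":
            yield potential("E", i, c), d_e, p
        else:
            p_e = design.p_e_given_c(c)
            if p_e > 0:
                yield 1, d_e, p * p_e
            if p_e < 1:
                yield 0, d_e, p * (1.0 - p_e)


def marginal_e_dt_deviation(pop: PopulationSpec, design: DesignSpec = OBSERVATIONAL) -> float:
    """Max deviation from the *unconditional* independence ``E ⊥ D-type``.

    Under marginal randomization with full follow-up this is zero — the
    distribution of D response types is comparable between arms — which is
    exactly the (full) exchangeability randomization buys.
    """
    def atoms():
        for t, c, p in pop.joint():
            i, j, _k = t
            if design.mode == "observational":
                yield potential("E", i, c), j, p
            else:
                p_e = design.p_e_given_c(c)
                if p_e > 0:
                    yield 1, j, p * p_e
                if p_e < 1:
                    yield 0, j, p * (1.0 - p_e)

    return _independence_deviation(atoms())


def check_all_conditions(
    pop: PopulationSpec,
    tol: float = INDEPENDENCE_TOL,
    design: DesignSpec = OBSERVATIONAL,
) -> dict[str, ConditionReport]:
    return {v: check_condition(pop, v, tol, design) for v in CONDITION_VARIANTS}


@dataclass(frozen=True)
class ChainViolation:
    """A population on which a stronger condition held but a weaker failed."""

    index: int
    stronger: str
    weaker: str
    reports: dict[str, ConditionReport]


def implication_audit(
    populations: Iterable[PopulationSpec],
    tol: float = INDEPENDENCE_TOL,
    design: DesignSpec = OBSERVATIONAL,
) -> list[ChainViolation]:
    """Assert the implication chain on a stream of populations.

    Whenever a stronger variant holds, every weaker variant must hold too.
    Indeterminate reports are skipped.  A non-empty return value is a bug in
    the checker (or a counterexample to the chain, which cannot exist).
    """
    violations = []
    for idx, pop in enumerate(populations):
        reports = check_all_conditions(pop, tol, design)
        for a_pos, stronger in enumerate(CONDITION_VARIANTS):
            for weaker in CONDITION_VARIANTS[a_pos + 1:]:
                ra, rb = reports[stronger], reports[weaker]
                if ra.holds is True and rb.holds is False:
                    violations.append(ChainViolation(idx, stronger, weaker, reports))
    return violations


# ---------------------------------------------------------------------------
# Bias gaps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapReport:
    """Signed discrepancy between two risk ratios (bias quantification)."""

    reference: RiskRatioValue
    comparison: RiskRatioValue
    difference: Optional[float]
    ratio: Optional[float]

    @property
    def determinate(self) -> bool:
        return self.difference is not None


def _gap(comparison: RiskRatioValue, reference: RiskRatioValue) -> GapReport:
    if not (comparison.defined and reference.defined):
        return GapReport(reference, comparison, None, None)
    return GapReport(
        reference,
        comparison,
        comparison.value - reference.value,
        comparison.value / reference.value,
    )


def confounding_gap(pop: PopulationSpec) -> GapReport:
    """Standardized associational RR (observational) minus causal RR.

    Zero whenever conditional exchangeability holds: standardization over
    the confounder then recovers the effect measure.  A nonzero gap is
    residual confounding that stratification on C cannot remove.
    """
    return _gap(std_rr(obs_cell_frequencies(pop)), causal_rr(pop))


def selection_gap(
    pop: PopulationSpec,
    measure_kind: str = "causal",
    design: DesignSpec = OBSERVATIONAL,
) -> GapReport:
    """S=1-restricted minus unrestricted risk ratio of the requested kind.

    ``associational`` compares the two ratios computed from the cells the
    design produces; ``causal`` compares the per-arm selection-restricted
    causal RR with the causal RR.  Zero gap is the non-selection-bias
    condition for that measure.
    """
    if measure_kind == "associational":
        cells = cell_frequencies(pop, design)
        return _gap(assoc_rr(cells, restrict_to_selected=True), assoc_rr(cells))
    if measure_kind == "causal":
        return _gap(causal_rr(pop, restrict_to_selected=True), causal_rr(pop))
    raise ValueError(f"measure_kind must be 'associational' or 'causal', got {measure_kind!r}")


# ---------------------------------------------------------------------------
# Positivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositivityReport:
    """Mass of each exposure-confounder combination, with zero cells flagged."""

    mass: dict[tuple[int, int], float]  # (e, c) -> P(E=e, C=c)
    zero_cells: tuple[tuple[int, int], ...]

    @property
    def holds(self) -> bool:
        return not self.zero_cells


def positivity_check(pop: PopulationSpec, design: DesignSpec = OBSERVATIONAL) -> PositivityReport:
    """Report ``P(E=e, C=c)`` for all four combinations under a design."""
    mass = {(e, c): 0.0 for e in (0, 1) for c in (0, 1)}
    for t, c, p in pop.joint():
        if design.mode == "observational":
            mass[(potential("E", t[0], c), c)] += p
        else:
            p_e = design.p_e_given_c(c)
            mass[(1, c)] += p * p_e
            mass[(0, c)] += p * (1.0 - p_e)
    zero = tuple(sorted(ec for ec, v in mass.items() if v <= 0))
    return PositivityReport(mass, zero)
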