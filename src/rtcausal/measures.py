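"""Associational, causal, standardized, and selection-restricted risk ratios.

Associational measures are properties of the observed cell frequencies a
design produces; causal measures are properties of the population's
potential outcomes, computed by g-computation over response types.  Keeping
the two computational routes separate is the point: their agreement or
disagreement *is* confounding/selection bias.

A ratio with an empty conditioning event or a zero denominator risk is
*undefined* — a first-class value carrying a reason, never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .population import (
    CellTable,
    DesignSpec,
    DSMarginal,
    PopulationSpec,
    cell_frequencies,
    ds_marginal,
)
from .response_types import potential


@dataclass(frozen=True)
class RiskRatioValue:
    """A risk ratio together with its component risks and defined-ness."""

    numerator_risk: Optional[float]
    denominator_risk: Optional[float]
    reason: Optional[str] = None  # set when undefined

    @property
    def defined(self) -> bool:
        return (
            self.reason is None
            and self.numerator_risk is not None
            and self.denominator_risk is not None
            and self.denominator_risk > 0
        )

    @property
    def value(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.numerator_risk / self.denominator_risk

    @staticmethod
    def undefined(reason: str) -> "RiskRatioValue":
        return RiskRatioValue(None, None, reason)

    @staticmethod
    def from_risks(num: float, den: float) -> "RiskRatioValue":
        if den <= 0:
            return RiskRatioValue(num, den, reason="denominator risk is zero")
        return RiskRatioValue(num, den)


def _conditional_risk(cells: CellTable, e: int, s: Optional[int], c: Optional[int]):
    """``P(D=1 | E=e [, S=s][, C=c])`` from cell frequencies, or None if the
    conditioning event has zero mass."""
    fixed = {"e": e}
    if s is not None:
        fixed["s"] = s
    if c is not None:
        fixed["c"] = c
    denom = cells.marginal(**fixed)
    if denom <= 0:
        return None
    return cells.marginal(d=1, **fixed) / denom


def assoc_rr(
    cells: CellTable,
    restrict_to_selected: bool = False,
    stratum: Optional[int] = None,
) -> RiskRatioValue:
    """Associational risk ratio from observed cell frequencies.

    ``P(D=1 | E=1, ...) / P(D=1 | E=0, ...)``, optionally restricted to the
    selected subpopulation ``S=1`` and/or a confounder stratum ``C=c``.
    """
    s = 1 if restrict_to_selected else None
    risks = {}
    for e in (1, 0):
        r = _conditional_risk(cells, e, s, stratum)
        if r is None:
            where = f"E={e}" + (", S=1" if s else "") + (f", C={stratum}" if stratum is not None else "")

            return RiskRatioValue.undefined(f"no individuals with {where}")
        risks[e] = r
    return RiskRatioValue.from_risks(risks[1], risks[0])


def std_rr(cells: CellTable) -> RiskRatioValue:
    """Confounder-standardized associational risk ratio.

    The weighted average of stratum-specific risks, weights being the total
    population confounder prevalence:
    ``[P(C) r(1,1) + P(C̄) r(1,0)] / [P(C) r(0,1) + P(C̄) r(0,0)]`` with
    ``r(e, c) = P(D=1 | E=e, C=c)``.  Requires the full-population table (no
    selection restriction): standardization addresses confounding only.
    """
    n = cells.total()
    if n <= 0:
        return RiskRatioValue.undefined("empty population")
    p_c = cells.marginal(c=1) / n
    num = den = 0.0
    for c, w in ((1, p_c), (0, 1.0 - p_c)):
        if w == 0.0:
            continue
        for e in (1, 0):
            r = _conditional_risk(cells, e, None, c)
            if r is None:
                return RiskRatioValue.undefined(f"empty stratum E={e}, C={c}")
            if e == 1:
                num += w * r
            else:
                den += w * r
    return RiskRatioValue.from_risks(num, den)


def causal_rr(
    pop: PopulationSpec,
    stratum: Optional[int] = None,
    restrict_to_selected: bool = False,
) -> RiskRatioValue:
    """Causal risk ratio ``P[D_{e=1}=1] / P[D_{e=0}=1]`` by g-computation.

    For each intervention arm ``e``, each type contributes
    ``P(C|type) D_{1e} + P(C̄|type) D_{0e}``; intervening on exposure leaves
    the confounder and the response types untouched.  With ``stratum`` set,
    risks condition on ``C=c`` (type weights re-normalized by Bayes).  With
    ``restrict_to_selected``, each arm is restricted to the individuals that
    arm itself would retain: ``S_{e, D_{c,e}} = 1``.
    """
    risks = {}
    for e in (1, 0):
        num = den = 0.0
        for t, c, p in pop.joint():
            if stratum is not None and c != stratum:
                continue
            d = potential("D", t[1], c, e)
            if restrict_to_selected:
                s = potential("S", t[2], e, d)
                if s == 0:
                    continue
            num += p * d
            den += p
        if den <= 0:
            what = f"stratum C={stratum}" if stratum is not None else "population"
            if restrict_to_selected:
                what += f" selected under intervention e={e}"
            return RiskRatioValue.undefined(f"empty {what}")
        risks[e] = num / den
    return RiskRatioValue.from_risks(risks[1], risks[0])


def causal_rr_from_ds(dsm: DSMarginal) -> RiskRatioValue:
    """Causal risk ratio from the DS-marginal, via response-type sums.

    Independent route used for cross-validation: the numerator is
    ``sum_{j: D11=1} P(C|Dj) P(Dj) + sum_{j: D01=1} P(C̄|Dj) P(Dj)`` and the
    denominator the analogue with ``D10`` / ``D00``.  The index sets are
    derived from the D-type bit vectors (every j with the bit set), not from
    any printed list.
    """
    # fold the S dimension into a D-type marginal with per-type P(C|Dj)
    mass_d: dict[int, float] = {}
    joint_c: dict[int, float] = {}
    for (j, _k), p in dsm.mass_ds.items():
        mass_d[j] = mass_d.get(j, 0.0) + p
        joint_c[j] = joint_c.get(j, 0.0) + p * dsm.c_given_ds[(j, _k)]
    num = den = 0.0
    for j, p_j in mass_d.items():
        pc_j = joint_c[j]  # P(C=1, Dj)
        num += potential("D", j, 1, 1) * pc_j + potential("D", j, 0, 1) * (p_j - pc_j)
        den += potential("D", j, 1, 0) * pc_j + potential("D", j, 0, 0) * (p_j - pc_j)
    return RiskRatioValue.from_risks(num, den)


@dataclass(frozen=True)
class ModificationFlags:
    """Stratum heterogeneity of association vs effect measures.

    ``True``/``False`` when both stratum measures are defined;
    ``None`` (indeterminate) otherwise.  The two notions are logically
    independent: association-measure modification neither implies nor is
    implied by effect-measure modification.
    """

    assoc_rr_modification: Optional[bool]
    causal_rr_modification: Optional[bool]


def _differs(a: RiskRatioValue, b: RiskRatioValue, tol: float) -> Optional[bool]:
    if not (a.defined and b.defined):
        return None
    scale = max(abs(a.value), abs(b.value), 1e-300)
    return abs(a.value - b.value) / scale > tol


def modification_flags(
    pop: PopulationSpec,
    design: DesignSpec,
    tol: float = 1e-9,
) -> ModificationFlags:
    """Compare stratum-specific associational and causal risk ratios."""
    cells = cell_frequencies(pop, design)
    assoc = {c: assoc_rr(cells, stratum=c) for c in (0, 1)}
    causal = {c: causal_rr(pop, stratum=c) for c in (0, 1)}
    return ModificationFlags(
        assoc_rr_modification=_differs(assoc[1], assoc[0], tol),
        causal_rr_modification=_differs(causal[1], causal[0], tol),
    )


@dataclass(frozen=True)
class MeasureReport:
    """Every risk-ratio measure for one population under one design."""

    assoc_rr: RiskRatioValue
    assoc_rr_s1: RiskRatioValue
    assoc_rr_by_c: tuple[RiskRatioValue, RiskRatioValue]  # (C=0, C=1)
    std_rr: RiskRatioValue
    causal_rr: RiskRatioValue
    causal_rr_s1: RiskRatioValue
    causal_rr_by_c: tuple[RiskRatioValue, RiskRatioValue]
    modification: ModificationFlags

    def to_dict(self) -> dict:
        def rr(v: RiskRatioValue) -> dict:
            return {
                "value": v.value,
                "numerator_risk": v.numerator_risk,
                "denominator_risk": v.denominator_risk,
                "defined": v.defined,
                "reason": v.reason,
            }

        return {
            "assoc_rr": rr(self.assoc_rr),
            "assoc_rr_s1": rr(self.assoc_rr_s1),
            "assoc_rr_c0": rr(self.assoc_rr_by_c[0]),
            "assoc_rr_c1": rr(self.assoc_rr_by_c[1]),
            "std_rr": rr(self.std_rr),
            "causal_rr": rr(self.causal_rr),
            "causal_rr_s1": rr(self.causal_rr_s1),
            "causal_rr_c0": rr(self.causal_rr_by_c[0]),
            "causal_rr_c1": rr(self.causal_rr_by_c[1]),
            "assoc_rr_modification": self.modification.assoc_rr_modification,
            "causal_rr_modification": self.modification.causal_rr_modification,
        }


def measure_report(pop: PopulationSpec, design: DesignSpec) -> MeasureReport:
    """Compute the full measure panel for a population under a design."""
    cells = cell_frequencies(pop, design)
    return MeasureReport(
        assoc_rr=assoc_rr(cells),
        assoc_rr_s1=assoc_rr(cells, restrict_to_selected=True),
        assoc_rr_by_c=(assoc_rr(cells, stratum=0), assoc_rr(cells, stratum=1)),
        std_rr=std_rr(cells),
        causal_rr=causal_rr(pop),
        causal_rr_s1=causal_rr(pop, restrict_to_selected=True),
        causal_rr_by_c=(causal_rr(pop, stratum=0), causal_rr(pop, stratum=1)),
        modification=modification_flags(pop, design),
    )
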