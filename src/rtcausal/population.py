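"""Causal populations over EDS response types and their observable data.

A :class:`PopulationSpec` is the complete causal truth about a closed
population of ``N`` individuals: a probability mass function over EDS
response types together with, for each type, the probability that the
confounder is present.  From this every observable quantity follows — the
expected frequencies of the 16 ``(E, D, C, S)`` cells under an observational
design or a randomized trial, and every associational or causal measure.

Cell frequencies are *expected* (real-valued) counts ``N * P``; integer
realizations come from :func:`sample`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .response_types import EDSType, potential, realize_observational, realize_rct

# dense lookup tables for vectorized sampling: value of each potential
# outcome indexed by (type index, *setting)
_E_TABLE = np.array(
    [[0, 0]] + [[potential("E", i, c) for c in (0, 1)] for i in range(1, 5)]
)
_D_TABLE = np.array(
    [[[0, 0], [0, 0]]]
    + [[[potential("D", j, c, e) for e in (0, 1)] for c in (0, 1)] for j in range(1, 17)]
)
_S_TABLE = np.array(
    [[[0, 0], [0, 0]]]
    + [[[potential("S", k, e, d) for d in (0, 1)] for e in (0, 1)] for k in range(1, 17)]
)

#: absolute tolerance on the total probability mass
MASS_TOL = 1e-9

Cell = tuple[int, int, int, int]  # (e, d, c, s)

#: the 16 observable cells, lexicographic
ALL_CELLS: tuple[Cell, ...] = tuple(
    (e, d, c, s) for e in (0, 1) for d in (0, 1) for c in (0, 1) for s in (0, 1)
)


class PopulationError(ValueError):
    """Invalid population or design specification."""


@dataclass(frozen=True)
class PopulationSpec:
    """Distribution of response types and confounder assignment.

    Parameters
    ----------
    n_total:
        Population size ``N`` (scales expected frequencies only; every
        probability or ratio derived from the spec is invariant in it).
    mass:
        Map ``(i, j, k) -> P_{EiDjSk}``, the prevalence of each EDS type.
        Unlisted types have zero mass.  Must sum to 1.
    c_given_type:
        Map ``(i, j, k) -> P(C=1 | EiDjSk)``.  Entries for zero-mass types
        are ignored; missing entries for positive-mass types are an error.
    """

    n_total: float
    mass: Mapping[tuple[int, int, int], float]
    c_given_type: Mapping[tuple[int, int, int], float]

    def __post_init__(self):
        errors = []
        if not self.n_total > 0:
            errors.append(f"n_total must be positive, got {self.n_total}")
        for t, p in self.mass.items():
            if not _valid_type(t):
                errors.append(f"invalid type triple {t!r}")
            if not 0.0 <= p <= 1.0:
                errors.append(f"mass[{t}] = {p} outside [0, 1]")
        total = math.fsum(self.mass.values())
        if abs(total - 1.0) > MASS_TOL:
            errors.append(f"type mass sums to {total!r}, not 1 (tolerance {MASS_TOL})")
        for t, p in self.mass.items():
            if p > 0 and t not in self.c_given_type:
                errors.append(f"missing c_given_type entry for positive-mass type {t}")
        for t, p in self.c_given_type.items():
            if not 0.0 <= p <= 1.0:
                errors.append(f"c_given_type[{t}] = {p} outside [0, 1]")
        if errors:
            raise PopulationError("invalid population spec:\n  " + "\n  ".join(errors))

    # -- convenience accessors ------------------------------------------------

    def support(self) -> list[EDSType]:
        """Types with positive mass, lexicographic order."""
        return sorted(EDSType(*t) for t, p in self.mass.items() if p > 0)

    def p_type(self, t: tuple[int, int, int]) -> float:
        return self.mass.get(tuple(t), 0.0)

    def p_c_given(self, t: tuple[int, int, int]) -> float:
        return self.c_given_type[tuple(t)]

    @property
    def p_c(self) -> float:
        """Marginal confounder prevalence ``P(C=1)``."""
        return math.fsum(p * self.c_given_type[t] for t, p in self.mass.items() if p > 0)

    def joint(self) -> Iterable[tuple[EDSType, int, float]]:
        """Atoms ``(type, c, probability)`` of the joint law of (type, C)."""
        for t in self.support():
            p, pc = self.p_type(t), self.p_c_given(t)
            for c, w in ((1, pc), (0, 1.0 - pc)):
                if w > 0:
                    yield t, c, self.p_type(t) * w

    def rescaled(self, n_total: float) -> "PopulationSpec":
        return PopulationSpec(n_total, self.mass, self.c_given_type)

    @classmethod
    def from_conditional(
        cls,
        n_total: float,
        p_c: float,
        mass_given_c: Mapping[tuple[int, int, int], float],
        mass_given_not_c: Mapping[tuple[int, int, int], float],
    ) -> "PopulationSpec":
        """Build a spec from the alternative parameterization
        ``{P(C), P(type | C=1), P(type | C=0)}`` via Bayes' rule (exact)."""
        if not 0.0 <= p_c <= 1.0:
            raise PopulationError(f"p_c = {p_c} outside [0, 1]")
        for name, m in (("mass_given_c", mass_given_c), ("mass_given_not_c", mass_given_not_c)):
            total = math.fsum(m.values())
            if abs(total - 1.0) > MASS_TOL:
                raise PopulationError(f"{name} sums to {total!r}, not 1")
        mass: dict[tuple[int, int, int], float] = {}
        cgt: dict[tuple[int, int, int], float] = {}
        for t in set(mass_given_c) | set(mass_given_not_c):
            joint1 = p_c * mass_given_c.get(t, 0.0)
            joint0 = (1.0 - p_c) * mass_given_not_c.get(t, 0.0)
            p = joint1 + joint0
            if p > 0:
                mass[t] = p
                cgt[t] = joint1 / p
        return cls(n_total, mass, cgt)


def _valid_type(t) -> bool:
    try:
        i, j, k = t
    except (TypeError, ValueError):
        return False
    return 1 <= i <= 4 and 1 <= j <= 16 and 1 <= k <= 16


@dataclass(frozen=True)
class DesignSpec:
    """How exposure arises: observed, or assigned by a trial.

    ``observational`` leaves exposure to the consistency mapping
    ``E = E_C``; ``rct_marginal`` assigns ``E ~ Bernoulli(p_exposed)``
    regardless of ``C``; ``rct_stratified`` assigns with probabilities
    ``p_exposed = (P(E=1|C=1), P(E=1|C=0))``.
    """

    mode: str = "observational"
    p_exposed: float | tuple[float, float] | None = None

    def __post_init__(self):
        if self.mode not in ("observational", "rct_marginal", "rct_stratified"):
            raise PopulationError(f"unknown design mode {self.mode!r}")
        if self.mode == "observational":
            if self.p_exposed is not None:
                raise PopulationError("observational design takes no p_exposed")
        elif self.mode == "rct_marginal":
            if not isinstance(self.p_exposed, (int, float)) or not 0 <= self.p_exposed <= 1:
                raise PopulationError("rct_marginal requires scalar p_exposed in [0, 1]")
        else:
            try:
                p1, p0 = self.p_exposed  # type: ignore[misc]
            except (TypeError, ValueError):
                raise PopulationError(
                    "rct_stratified requires p_exposed = (P(E|C=1), P(E|C=0))"
                ) from None
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise PopulationError("stratified exposure probabilities must lie in [0, 1]")

    def p_e_given_c(self, c: int) -> float:
        """Assigned exposure probability in stratum ``c`` (trial designs only)."""
        if self.mode == "rct_marginal":
            return float(self.p_exposed)  # type: ignore[arg-type]
        if self.mode == "rct_stratified":
            return float(self.p_exposed[c == 0])  # type: ignore[index]
        raise PopulationError("observational design does not assign exposure")


OBSERVATIONAL = DesignSpec("observational")


@dataclass
class CellTable:
    """Expected frequencies of the 16 observable ``(E, D, C, S)`` cells."""

    cells: dict[Cell, float]
    n_total: float

    def __post_init__(self):
        full = {cell: float(self.cells.get(cell, 0.0)) for cell in ALL_CELLS}
        if any(v < -1e-12 for v in full.values()):
            raise PopulationError("negative cell frequency")
        self.cells = full

    def __getitem__(self, cell: Cell) -> float:
        return self.cells[cell]

    def total(self) -> float:
        return math.fsum(self.cells.values())

    def marginal(self, **fixed: int) -> float:
        """Total frequency of cells matching the given e/d/c/s values."""
        axes = "edcs"
        out = 0.0
        for cell, v in self.cells.items():
            if all(cell[axes.index(a)] == val for a, val in fixed.items()):
                out += v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"e": e, "d": d, "c": c, "s": s, "frequency": self.cells[(e, d, c, s)]}
            for (e, d, c, s) in ALL_CELLS
        ]
        return pd.DataFrame(rows)


def obs_cell_frequencies(pop: PopulationSpec) -> CellTable:
    """Theoretical cell frequencies of an observational study.

    Each type contributes mass to at most two cells — the one realized when
    its confounder is present (weight ``P(C|type)``) and the one realized
    when absent (weight ``1 - P(C|type)``).
    """
    cells: dict[Cell, float] = {cell: 0.0 for cell in ALL_CELLS}
    for t, c, p in pop.joint():
        e, d, s = realize_observational(t, c)
        cells[(e, d, c, s)] += pop.n_total * p
    return CellTable(cells, pop.n_total)


def ds_marginal(pop: PopulationSpec) -> "DSMarginal":
    """Marginalize the E-type dimension out of a population spec."""
    mass_ds: dict[tuple[int, int], float] = {}
    joint_c: dict[tuple[int, int], float] = {}
    for t, p in pop.mass.items():
        if p <= 0:
            continue
        jk = (t[1], t[2])
        mass_ds[jk] = mass_ds.get(jk, 0.0) + p
        joint_c[jk] = joint_c.get(jk, 0.0) + p * pop.p_c_given(t)
    c_given_ds = {jk: joint_c[jk] / mass_ds[jk] for jk in mass_ds}
    return DSMarginal(mass_ds, c_given_ds)


@dataclass(frozen=True)
class DSMarginal:
    """Distribution of ``(D type, S type)`` with per-pair confounder probability.

    Sufficient for every trial quantity: randomization makes the E type
    irrelevant.
    """

    mass_ds: Mapping[tuple[int, int], float]
    c_given_ds: Mapping[tuple[int, int], float]

    def rct_cell_frequencies(self, design: DesignSpec, n_total: float) -> CellTable:
        if design.mode == "observational":
            raise PopulationError("trial cell frequencies require an rct design")
        cells: dict[Cell, float] = {cell: 0.0 for cell in ALL_CELLS}
        for jk, p_jk in self.mass_ds.items():
            pc = self.c_given_ds[jk]
            for c, w_c in ((1, pc), (0, 1.0 - pc)):
                for e in (0, 1):
                    p_e = design.p_e_given_c(c)
                    w_e = p_e if e == 1 else 1.0 - p_e
                    if w_c * w_e == 0.0:
                        continue
                    d, s = realize_rct(jk[0], jk[1], c, e)
                    cells[(e, d, c, s)] += n_total * w_e * w_c * p_jk
        return CellTable(cells, n_total)


def rct_cell_frequencies(pop: PopulationSpec, design: DesignSpec) -> CellTable:
    """Theoretical cell frequencies of a randomized trial on this population.

    Cell ``(e, d, c, s)`` receives
    ``N * P(E=e | C=c) * sum over DS pairs realizing (d, s) of P(C=c, DjSk)``.
    """
    return ds_marginal(pop).rct_cell_frequencies(design, pop.n_total)


def cell_frequencies(pop: PopulationSpec, design: DesignSpec) -> CellTable:
    """Cell frequencies under either design kind."""
    if design.mode == "observational":
        return obs_cell_frequencies(pop)
    return rct_cell_frequencies(pop, design)


@dataclass(frozen=True)
class RedistributionReport:
    """Residuals of the observational-to-trial redistribution identities."""

    max_residual: float
    n_identities: int
    crosses_c_strata: bool  # always False: reassignment of E preserves C

    @property
    def ok(self) -> bool:
        return self.max_residual <= 1e-9 and not self.crosses_c_strata


def redistribution_audit(pop: PopulationSpec, design: DesignSpec) -> RedistributionReport:
    """Verify that trial frequencies are a redistribution of observational ones.

    For every DS pair ``(j, k)`` and every arm/stratum ``(e, c)``, the
    observational mass of that pair in stratum ``c`` (accumulated over E
    types) times the assignment probability ``P(E=e | C=c)`` must equal the
    trial expression ``N * P(E=e|C=c) * P(C=c | DjSk) * P_{DjSk}``.
    Individuals never move across confounder strata, because the confounder
    is determined before exposure is assigned.
    """
    if design.mode == "observational":
        raise PopulationError("redistribution audit requires an rct design")
    n = pop.n_total
    # observational stratum mass of each DS pair, summed over E types
    obs_mass: dict[tuple[int, int, int], float] = {}
    for t, c, p in pop.joint():
        key = (t[1], t[2], c)
        obs_mass[key] = obs_mass.get(key, 0.0) + p
    dsm = ds_marginal(pop)
    max_resid, count = 0.0, 0
    for jk, p_jk in dsm.mass_ds.items():
        pc = dsm.c_given_ds[jk]
        for c, w_c in ((1, pc), (0, 1.0 - pc)):
            for e in (0, 1):
                p_e = design.p_e_given_c(c)
                w_e = p_e if e == 1 else 1.0 - p_e
                lhs = w_e * n * obs_mass.get((jk[0], jk[1], c), 0.0)
                rhs = n * w_e * w_c * p_jk
                max_resid = max(max_resid, abs(lhs - rhs))
                count += 1
    return RedistributionReport(max_resid, count, crosses_c_strata=False)


def sample(
    pop: PopulationSpec,
    design: DesignSpec,
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw ``n`` i.i.d. individual records from the population under a design.

    Columns: ``id, e_type, d_type, s_type, c, e, d, s``.  Exposure follows
    consistency under the observational design and Bernoulli assignment in a
    trial.  Reproducible given the seed.
    """
    if n < 1:
        raise PopulationError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    types = pop.support()
    probs = np.array([pop.p_type(t) for t in types])
    probs = probs / probs.sum()
    idx = rng.choice(len(types), size=n, p=probs)
    pc = np.array([pop.p_c_given(t) for t in types])[idx]
    c = (rng.random(n) < pc).astype(int)
    type_arr = np.array(types)[idx]
    i_arr, j_arr, k_arr = type_arr[:, 0], type_arr[:, 1], type_arr[:, 2]
    if design.mode == "observational":
        e = _E_TABLE[i_arr, c]
    else:
        p_e = np.where(c == 1, design.p_e_given_c(1), design.p_e_given_c(0))
        e = (rng.random(n) < p_e).astype(int)
    d = _D_TABLE[j_arr, c, e]
    s = _S_TABLE[k_arr, e, d]
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "e_type": i_arr,
            "d_type": j_arr,
            "s_type": k_arr,
            "c": c,
            "e": e,
            "d": d,
            "s": s,
        }
    )


def empirical_cell_table(records: pd.DataFrame, n_total: float | None = None) -> CellTable:
    """Cell counts of sampled records, as a :class:`CellTable`."""
    counts = records.groupby(["e", "d", "c", "s"]).size()
    cells = {tuple(map(int, key)): float(v) for key, v in counts.items()}
    return CellTable(cells, n_total if n_total is not None else float(len(records)))
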