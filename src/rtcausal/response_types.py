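"""Potential-outcome response types for binary exposure, disease, and selection.

The causal system has four binary variables: a confounder ``C``, an exposure
``E`` (caused by ``C``), a disease outcome ``D`` (caused by ``C`` and ``E``),
and a selection indicator ``S`` (caused by ``E`` and ``D``).  Each individual
carries a deterministic *response type* for every caused variable: the full
vector of potential outcomes that variable would take under every joint
setting of its manipulable causes.

* An **E type** is the pair ``(E_1, E_0)`` — potential exposure when the
  confounder is set to 1 or 0.  There are 4 E types.
* A **D type** is the quadruple ``(D_11, D_01, D_10, D_00)`` — potential
  disease under each joint setting ``(c, e)``.  There are 16 D types.
* An **S type** is the quadruple ``(S_11, S_01, S_10, S_00)`` — potential
  selection under each joint setting ``(e, d)``.  There are 16 S types.

Types are indexed 1..4 / 1..16 in descending binary order of their bit
vectors (index 1 is all-ones, the "doomed" type; the last index is all-zeros,
the "immune" type), so that ``index = max + 1 - int(bits, base=2)``.

A full *EDS type* is a triple of indices; the unrestricted cross product has
``4 * 16 * 16 = 1024`` members.  Monotonicity and no-additive-interaction
restrictions cut this down to ``3 * 4 * 4 = 48``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Literal, NamedTuple, Sequence

Kind = Literal["E", "D", "S"]

#: number of potential outcomes per kind (2 for E, 4 for D and S)
_N_BITS = {"E": 2, "D": 4, "S": 4}
#: number of response types per kind
N_TYPES = {"E": 4, "D": 16, "S": 16}

#: joint settings of the causes, in the column order of the bit vector.
#: For D the setting is (c, e); for S it is (e, d); for E it is (c,).
_SETTINGS = {
    "E": ((1,), (0,)),
    "D": ((1, 1), (0, 1), (1, 0), (0, 0)),
    "S": ((1, 1), (0, 1), (1, 0), (0, 0)),
}


def _check_kind(kind: str) -> str:
    if kind not in _N_BITS:
        raise ValueError(f"unknown kind {kind!r}; expected one of 'E', 'D', 'S'")
    return kind


def _check_index(kind: Kind, index: int) -> int:
    n = N_TYPES[_check_kind(kind)]
    if not isinstance(index, (int,)) or isinstance(index, bool) or not 1 <= index <= n:
        raise ValueError(f"{kind} type index must be an integer in 1..{n}, got {index!r}")
    return index


def index_to_bits(kind: Kind, index: int) -> tuple[int, ...]:
    """Bit vector of potential outcomes for response type ``index`` of ``kind``.

    Bits are ordered as in the enumeration tables: ``(E_1, E_0)`` for E,
    ``(D_11, D_01, D_10, D_00)`` for D, ``(S_11, S_01, S_10, S_00)`` for S.
    """
    _check_index(kind, index)
    n_bits = _N_BITS[kind]
    value = N_TYPES[kind] - index  # descending order: index 1 <-> all ones
    return tuple((value >> (n_bits - 1 - i)) & 1 for i in range(n_bits))


def bits_to_index(kind: Kind, bits: Sequence[int]) -> int:
    """Inverse of :func:`index_to_bits`."""
    _check_kind(kind)
    n_bits = _N_BITS[kind]
    if len(bits) != n_bits or any(b not in (0, 1) for b in bits):
        raise ValueError(f"{kind} bit vector must be {n_bits} bits of 0/1, got {bits!r}")
    value = 0
    for b in bits:
        value = (value << 1) | b
    return N_TYPES[kind] - value


def potential(kind: Kind, index: int, *setting: int) -> int:
    """Potential outcome of a response type under a counterfactual setting.

    ``potential("E", i, c)`` is :math:`E_c`; ``potential("D", j, c, e)`` is
    :math:`D_{ce}`; ``potential("S", k, e, d)`` is :math:`S_{ed}`.
    """
    bits = index_to_bits(kind, index)
    settings = _SETTINGS[kind]
    if len(setting) != len(settings[0]) or any(v not in (0, 1) for v in setting):
        raise ValueError(
            f"setting for kind {kind} must be {len(settings[0])} values in {{0,1}}, "
            f"got {setting!r}"
        )
    return bits[settings.index(tuple(setting))]


def is_monotone(kind: Kind, index: int) -> bool:
    """Whether the type is consistent with positive monotonic effects.

    A type is monotone when its potential outcome is non-decreasing in every
    setting argument: for D, :math:`D_{ce} \\ge D_{c'e'}` whenever
    :math:`c \\ge c'` and :math:`e \\ge e'` (componentwise), and analogously
    for S; for E, :math:`E_1 \\ge E_0`.  Monotonicity rules out "preventive"
    response types (E type 3; D/S types 3, 5, 7, 9–15).
    """
    bits = index_to_bits(kind, index)
    settings = _SETTINGS[kind]
    for (a, sa), (b, sb) in itertools.combinations(zip(bits, settings), 2):
        if all(x >= y for x, y in zip(sa, sb)) and a < b:
            return False
        if all(x <= y for x, y in zip(sa, sb)) and a > b:
            return False
    return True


def additive_interaction(kind: Kind, index: int) -> int:
    """Individual-level additive interaction contrast of a D or S type.

    For a D type this is :math:`D_{11} - D_{01} - D_{10} + D_{00}`; zero
    means the two causes act additively for that individual.  Undefined for
    E types, which have a single cause.
    """
    _check_kind(kind)
    if kind == "E":
        raise ValueError("additive interaction is undefined for E types (single cause)")
    b = index_to_bits(kind, index)
    return b[0] - b[1] - b[2] + b[3]


@dataclass(frozen=True)
class RestrictionSet:
    """Optional a-priori restrictions on the admissible response types.

    Each flag removes types: ``monotone_E`` keeps E types with a positive
    monotonic confounder effect (3 of 4); ``monotone_D`` keeps monotone D
    types (6 of 16); ``no_additive_interaction_D`` keeps D types with zero
    individual-level additive interaction; likewise for S.  Monotonicity and
    no-interaction together keep D (or S) types {1, 4, 6, 16}.
    """

    monotone_E: bool = False
    monotone_D: bool = False
    no_additive_interaction_D: bool = False
    monotone_S: bool = False
    no_additive_interaction_S: bool = False

    @classmethod
    def all(cls) -> "RestrictionSet":
        return cls(True, True, True, True, True)

    def allowed(self, kind: Kind) -> list[int]:
        """Admissible type indices of ``kind`` under these restrictions."""
        _check_kind(kind)
        out = []
        for i in range(1, N_TYPES[kind] + 1):
            if kind == "E":
                if self.monotone_E and not is_monotone("E", i):
                    continue
            elif kind == "D":
                if self.monotone_D and not is_monotone("D", i):
                    continue
                if self.no_additive_interaction_D and additive_interaction("D", i) != 0:
                    continue
            else:
                if self.monotone_S and not is_monotone("S", i):
                    continue
                if self.no_additive_interaction_S and additive_interaction("S", i) != 0:
                    continue
            out.append(i)
        return out


class EDSType(NamedTuple):
    """A full response type: indices of the E, D, and S components."""

    e_type: int
    d_type: int
    s_type: int


def enumerate_types(restrictions: RestrictionSet | None = None) -> list[EDSType]:
    """All admissible EDS types, in lexicographic index order.

    With no restrictions this is the full 1,024-element cross product; with
    all five restriction flags exactly 48 types remain
    (E in {1,2,4} x D in {1,4,6,16} x S in {1,4,6,16}).
    """
    r = restrictions or RestrictionSet()
    return [
        EDSType(i, j, k)
        for i in r.allowed("E")
        for j in r.allowed("D")
        for k in r.allowed("S")
    ]


# ---------------------------------------------------------------------------
# Compound (nested) potential outcomes and the consistency mapping
# ---------------------------------------------------------------------------

def compound_d(e_type: int, d_type: int, c: int, c_prime: int) -> int:
    """Compound potential disease :math:`D_{c, E_{c'}}`.

    The disease an individual would suffer if the confounder were set to
    ``c`` while their exposure took the value it would have under confounder
    setting ``c_prime``.  The four ``(c, c_prime)`` combinations give the
    compound-D columns of the joint enumeration; only the diagonal
    ``c == c_prime`` combinations are ever realized under consistency.
    """
    return potential("D", d_type, c, potential("E", e_type, c_prime))


def compound_s(
    e_type: int, d_type: int, s_type: int, c: int, c_prime: int, c_dprime: int
) -> int:
    """Compound potential selection :math:`S_{E_c, D_{c', E_{c''}}}`.

    Eight combinations exist; the diagonal ``c == c_prime == c_dprime`` gives
    the individual's selection status when the confounder equals ``c``.
    """
    e = potential("E", e_type, c)
    d = compound_d(e_type, d_type, c_prime, c_dprime)
    return potential("S", s_type, e, d)


def realize_observational(t: EDSType | tuple[int, int, int], c: int) -> tuple[int, int, int]:
    """Observed ``(e, d, s)`` of an individual of type ``t`` with confounder ``c``.

    The consistency mapping: ``e = E_c``, ``d = D_{c,e}``, ``s = S_{e,d}``.
    Each EDS type therefore occupies at most two of the 16 observable
    ``(E, D, C, S)`` cells, one per confounder value.
    """
    i, j, k = t
    if c not in (0, 1):
        raise ValueError(f"c must be 0 or 1, got {c!r}")
    e = potential("E", i, c)
    d = potential("D", j, c, e)
    s = potential("S", k, e, d)
    return e, d, s


def realize_rct(d_type: int, s_type: int, c: int, e: int) -> tuple[int, int]:
    """Observed ``(d, s)`` in a trial that assigns exposure ``e`` with confounder ``c``.

    Randomization overrides the E response type, so only the D and S types
    matter: ``d = D_{c,e}``, ``s = S_{e,d}``.  A DS type pair occupies at
    most four observable cells, one per ``(c, e)`` combination.
    """
    if c not in (0, 1) or e not in (0, 1):
        raise ValueError(f"c and e must be 0 or 1, got c={c!r}, e={e!r}")
    d = potential("D", d_type, c, e)
    s = potential("S", s_type, e, d)
    return d, s


# ---------------------------------------------------------------------------
# Realization status (which counterfactual quantities are observable)
# ---------------------------------------------------------------------------

def is_realized(
    t: EDSType | tuple[int, int, int],
    column: str,
    setting: tuple[int, ...],
) -> bool:
    """Whether a (compound) potential outcome is realizable under consistency.

    ``column`` selects the family: ``"E"`` (setting ``(c,)``), ``"D"``
    (setting ``(c, e)``), ``"S"`` (setting ``(e, d)``), ``"compound_d"``
    (setting ``(c, c')``), or ``"compound_s"`` (setting ``(c, c', c'')``).
    An entry is realizable when some confounder value ``c`` in {0, 1} makes
    the observed variables coincide with that counterfactual setting.  In
    printed enumerations the never-realized entries are the parenthesized
    ones.
    """
    if column == "E":
        return True  # both E_1 and E_0 are realized (one per confounder value)
    if column == "D":
        # D_{ce} observable iff e matches the exposure realized under C=c
        return any(setting == (c, realize_observational(t, c)[0]) for c in (0, 1))
    if column == "S":
        # S_{ed} observable iff (e, d) matches the pair realized under some C=c
        return any(setting == realize_observational(t, c)[:2] for c in (0, 1))
    if column == "compound_d":
        return setting[0] == setting[1]
    if column == "compound_s":
        return setting[0] == setting[1] == setting[2]
    raise ValueError(f"unknown column family {column!r}")


# ---------------------------------------------------------------------------
# Tabular rendering of the joint enumeration
# ---------------------------------------------------------------------------

#: column order of the joint enumeration table
TABLE_COLUMNS = (
    "e_type", "d_type", "s_type",
    "E1", "E0",
    "D11", "D01", "D10", "D00",
    "D1E1", "D1E0", "D0E1", "D0E0",
    "S11", "S01", "S10", "S00",
    "SEL_C1", "SEL_C0",
)


def type_table_row(t: EDSType | tuple[int, int, int]) -> dict[str, int]:
    """All potential outcomes, compound potential outcomes, and selection
    status of one EDS type, keyed by :data:`TABLE_COLUMNS`."""
    i, j, k = EDSType(*t)
    row: dict[str, int] = {"e_type": i, "d_type": j, "s_type": k}
    row["E1"], row["E0"] = index_to_bits("E", i)
    row["D11"], row["D01"], row["D10"], row["D00"] = index_to_bits("D", j)
    for c, cp in ((1, 1), (1, 0), (0, 1), (0, 0)):
        row[f"D{c}E{cp}"] = compound_d(i, j, c, cp)
    row["S11"], row["S01"], row["S10"], row["S00"] = index_to_bits("S", k)
    row["SEL_C1"] = compound_s(i, j, k, 1, 1, 1)
    row["SEL_C0"] = compound_s(i, j, k, 0, 0, 0)
    return row


def type_table(restrictions: RestrictionSet | None = None) -> "Iterator[dict[str, int]]":
    """Rows of the joint enumeration table for the admissible types."""
    for t in enumerate_types(restrictions):
        yield type_table_row(t)
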