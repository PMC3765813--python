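"""Unit and property tests for the response-type algebra."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtcausal import (
    EDSType,
    RestrictionSet,
    additive_interaction,
    bits_to_index,
    compound_d,
    compound_s,
    enumerate_types,
    index_to_bits,
    is_monotone,
    is_realized,
    potential,
    realize_observational,
    realize_rct,
    type_table_row,
)
from rtcausal.response_types import N_TYPES, TABLE_COLUMNS

# ---------------------------------------------------------------------------
# The full restricted enumeration, frozen as printed: 48 rows of
# "i j k | E1 E0 | D11 D01 D10 D00 | D1E1 D1E0 D0E1 D0E0 | S11 S01 S10 S00 |
#  selection status (C=1, C=0)".  Parenthesized entries are potential
# outcomes that no confounder value can realize under consistency.
# ---------------------------------------------------------------------------
RESTRICTED_TABLE = [
    "1 1 1 1 1 1 1 (1) (1) 1 (1) (1) 1 1 (1) (1) (1) 1 1",
    "1 1 4 1 1 1 1 (1) (1) 1 (1) (1) 1 1 (1) (0) (0) 1 1",
    "1 1 6 1 1 1 1 (1) (1) 1 (1) (1) 1 1 (0) (1) (0) 1 1",
    "1 1 16 1 1 1 1 (1) (1) 1 (1) (1) 1 0 (0) (0) (0) 0 0",
    "1 4 1 1 1 1 1 (0) (0) 1 (1) (1) 1 1 (1) (1) (1) 1 1",
    "1 4 4 1 1 1 1 (0) (0) 1 (1) (1) 1 1 (1) (0) (0) 1 1",
    "1 4 6 1 1 1 1 (0) (0) 1 (1) (1) 1 1 (0) (1) (0) 1 1",
    "1 4 16 1 1 1 1 (0) (0) 1 (1) (1) 1 0 (0) (0) (0) 0 0",
    "1 6 1 1 1 1 0 (1) (0) 1 (1) (0) 0 1 (1) 1 (1) 1 1",
    "1 6 4 1 1 1 0 (1) (0) 1 (1) (0) 0 1 (1) 0 (0) 1 0",
    "1 6 6 1 1 1 0 (1) (0) 1 (1) (0) 0 1 (0) 1 (0) 1 1",
    "1 6 16 1 1 1 0 (1) (0) 1 (1) (0) 0 0 (0) 0 (0) 0 0",
    "1 16 1 1 1 0 0 (0) (0) 0 (0) (0) 0 1 (1) 1 (1) 1 1",
    "1 16 4 1 1 0 0 (0) (0) 0 (0) (0) 0 1 (1) 0 (0) 0 0",
    "1 16 6 1 1 0 0 (0) (0) 0 (0) (0) 0 1 (0) 1 (0) 1 1",
    "1 16 16 1 1 0 0 (0) (0) 0 (0) (0) 0 0 (0) 0 (0) 0 0",
    "2 1 1 1 0 1 (1) (1) 1 1 (1) (1) 1 1 1 (1) (1) 1 1",
    "2 1 4 1 0 1 (1) (1) 1 1 (1) (1) 1 1 1 (0) (0) 1 1",
    "2 1 6 1 0 1 (1) (1) 1 1 (1) (1) 1 1 0 (1) (0) 1 0",
    "2 1 16 1 0 1 (1) (1) 1 1 (1) (1) 1 0 0 (0) (0) 0 0",
    "2 4 1 1 0 1 (1) (0) 0 1 (0) (1) 0 1 (1) (1) 1 1 1",
    "2 4 4 1 0 1 (1) (0) 0 1 (0) (1) 0 1 (1) (0) 0 1 0",
    "2 4 6 1 0 1 (1) (0) 0 1 (0) (1) 0 1 (0) (1) 0 1 0",
    "2 4 16 1 0 1 (1) (0) 0 1 (0) (1) 0 0 (0) (0) 0 0 0",
    "2 6 1 1 0 1 (0) (1) 0 1 (1) (0) 0 1 (1) (1) 1 1 1",
    "2 6 4 1 0 1 (0) (1) 0 1 (1) (0) 0 1 (1) (0) 0 1 0",
    "2 6 6 1 0 1 (0) (1) 0 1 (1) (0) 0 1 (0) (1) 0 1 0",
    "2 6 16 1 0 1 (0) (1) 0 1 (1) (0) 0 0 (0) (0) 0 0 0",
    "2 16 1 1 0 0 (0) (0) 0 0 (0) (0) 0 (1) (1) 1 1 1 1",
    "2 16 4 1 0 0 (0) (0) 0 0 (0) (0) 0 (1) (1) 0 0 0 0",
    "2 16 6 1 0 0 (0) (0) 0 0 (0) (0) 0 (1) (0) 1 0 1 0",
    "2 16 16 1 0 0 (0) (0) 0 0 (0) (0) 0 (0) (0) 0 0 0 0",
    "4 1 1 0 0 (1) (1) 1 1 1 (1) (1) 1 (1) 1 (1) (1) 1 1",
    "4 1 4 0 0 (1) (1) 1 1 1 (1) (1) 1 (1) 1 (0) (0) 1 1",
    "4 1 6 0 0 (1) (1) 1 1 1 (1) (1) 1 (1) 0 (1) (0) 0 0",
    "4 1 16 0 0 (1) (1) 1 1 1 (1) (1) 1 (0) 0 (0) (0) 0 0",
    "4 4 1 0 0 (1) (1) 0 0 0 (0) (0) 0 (1) (1) (1) 1 1 1",
    "4 4 4 0 0 (1) (1) 0 0 0 (0) (0) 0 (1) (1) (0) 0 0 0",
    "4 4 6 0 0 (1) (1) 0 0 0 (0) (0) 0 (1) (0) (1) 0 0 0",
    "4 4 16 0 0 (1) (1) 0 0 0 (0) (0) 0 (0) (0) (0) 0 0 0",
    "4 6 1 0 0 (1) (0) 1 0 1 (1) (0) 0 (1) 1 (1) 1 1 1",
    "4 6 4 0 0 (1) (0) 1 0 1 (1) (0) 0 (1) 1 (0) 0 1 0",
    "4 6 6 0 0 (1) (0) 1 0 1 (1) (0) 0 (1) 0 (1) 0 0 0",
    "4 6 16 0 0 (1) (0) 1 0 1 (1) (0) 0 (0) 0 (0) 0 0 0",
    "4 16 1 0 0 (0) (0) 0 0 0 (0) (0) 0 (1) (1) (1) 1 1 1",
    "4 16 4 0 0 (0) (0) 0 0 0 (0) (0) 0 (1) (1) (0) 0 0 0",
    "4 16 6 0 0 (0) (0) 0 0 0 (0) (0) 0 (1) (0) (1) 0 0 0",
    "4 16 16 0 0 (0) (0) 0 0 0 (0) (0) 0 (0) (0) (0) 0 0 0",
]

#: column -> (realization family, setting) for the parenthesization check
_REALIZATION_KEY = {
    "E1": ("E", (1,)), "E0": ("E", (0,)),
    "D11": ("D", (1, 1)), "D01": ("D", (0, 1)), "D10": ("D", (1, 0)), "D00": ("D", (0, 0)),
    "D1E1": ("compound_d", (1, 1)), "D1E0": ("compound_d", (1, 0)),
    "D0E1": ("compound_d", (0, 1)), "D0E0": ("compound_d", (0, 0)),
    "S11": ("S", (1, 1)), "S01": ("S", (0, 1)), "S10": ("S", (1, 0)), "S00": ("S", (0, 0)),
    "SEL_C1": ("compound_s", (1, 1, 1)), "SEL_C0": ("compound_s", (0, 0, 0)),
}


#: reference-table entries whose printed parenthesization contradicts the
#: consistency mapping: an always-exposed, never-diseased individual (E type
#: 1, D type 16) never realizes the selection setting (e=1, d=1), yet the
#: printed rows leave S11 unparenthesized (they carry the same pattern as the
#: E1/D6 rows, whose realized settings genuinely are S11 and S10).  The
#: engine follows the consistency definition.
KNOWN_REALIZATION_SLIPS = {((1, 16, k), "S11") for k in (1, 4, 6, 16)}


def _parse_reference_row(line: str):
    toks = line.split()
    values = {
        col: int(tok.strip("()"))
        for col, tok in zip(TABLE_COLUMNS, toks)
    }
    realized = {
        col: not tok.startswith("(")
        for col, tok in zip(TABLE_COLUMNS, toks)
        if col in _REALIZATION_KEY
    }
    return values, realized


class TestIndexBijection:
    @pytest.mark.parametrize("kind", ["E", "D", "S"])
    def test_round_trip(self, kind):
        for index in range(1, N_TYPES[kind] + 1):
            assert bits_to_index(kind, index_to_bits(kind, index)) == index

    def test_descending_binary_order(self):
        # index 1 is all-ones, the last index all-zeros
        assert index_to_bits("E", 1) == (1, 1)
        assert index_to_bits("E", 4) == (0, 0)
        assert index_to_bits("D", 1) == (1, 1, 1, 1)
        assert index_to_bits("D", 16) == (0, 0, 0, 0)

    @pytest.mark.parametrize(
        "kind,index,bits",
        [("D", 6, (1, 0, 1, 0)), ("E", 2, (1, 0)), ("S", 4, (1, 1, 0, 0))],
    )
    def test_reference_rows(self, kind, index, bits):
        assert index_to_bits(kind, index) == bits

    @pytest.mark.parametrize("kind,index", [("E", 0), ("E", 5), ("D", 17), ("S", -1), ("Q", 1)])
    def test_out_of_range_rejected(self, kind, index):
        with pytest.raises(ValueError):
            index_to_bits(kind, index)


class TestPotential:
    def test_e_type_2_tracks_confounder(self):
        assert potential("E", 2, 1) == 1
        assert potential("E", 2, 0) == 0

    def test_d_type_6_entries(self):
        assert [potential("D", 6, c, e) for c, e in ((1, 1), (0, 1), (1, 0), (0, 0))] == [1, 0, 1, 0]

    def test_all_zero_type_everywhere_zero(self):
        assert all(potential("S", 16, e, d) == 0 for e in (0, 1) for d in (0, 1))

    def test_malformed_setting_rejected(self):
        with pytest.raises(ValueError):
            potential("D", 6, 1)  # D needs (c, e)
        with pytest.raises(ValueError):
            potential("E", 2, 2)


class TestRestrictions:
    def test_monotone_e_excludes_only_type_3(self):
        assert [i for i in range(1, 5) if is_monotone("E", i)] == [1, 2, 4]

    def test_monotone_d_retention_set(self):
        kept = [j for j in range(1, 17) if is_monotone("D", j)]
        assert kept == [1, 2, 4, 6, 8, 16]
        excluded = sorted(set(range(1, 17)) - set(kept))
        assert excluded == [3, 5, 7] + list(range(9, 16))

    def test_additive_interaction_values(self):
        assert additive_interaction("D", 1) == 0
        assert additive_interaction("D", 2) == -1
        assert additive_interaction("D", 8) == 1
        with pytest.raises(ValueError):
            additive_interaction("E", 1)

    def test_monotone_and_no_interaction_keep_four(self):
        for kind in ("D", "S"):
            kept = [
                j
                for j in range(1, 17)
                if is_monotone(kind, j) and additive_interaction(kind, j) == 0
            ]
            assert kept == [1, 4, 6, 16]

    @pytest.mark.parametrize(
        "restrictions,count",
        [
            (RestrictionSet(), 1024),
            (RestrictionSet(monotone_E=True), 768),
            (RestrictionSet.all(), 48),
        ],
    )
    def test_enumeration_counts(self, restrictions, count):
        types = enumerate_types(restrictions)
        assert len(types) == count
        assert types == sorted(types)  # deterministic lexicographic order

    def test_restricted_support(self):
        types = enumerate_types(RestrictionSet.all())
        assert {t.e_type for t in types} == {1, 2, 4}
        assert {t.d_type for t in types} == {1, 4, 6, 16}
        assert {t.s_type for t in types} == {1, 4, 6, 16}


class TestRestrictedTableReconstruction:
    """The full 48-row joint enumeration is reproduced bit for bit,
    including compound potential outcomes, selection-status columns, and
    which entries are realizable under consistency."""

    def test_row_count_and_order(self):
        types = enumerate_types(RestrictionSet.all())
        ref = [tuple(int(x) for x in line.split()[:3]) for line in RESTRICTED_TABLE]
        assert [tuple(t) for t in types] == ref

    @pytest.mark.parametrize("line", RESTRICTED_TABLE, ids=lambda l: "-".join(l.split()[:3]))
    def test_row_values_and_realization(self, line):
        values, realized = _parse_reference_row(line)
        t = EDSType(values["e_type"], values["d_type"], values["s_type"])
        computed = type_table_row(t)
        assert computed == values
        for col, expected in realized.items():
            family, setting = _REALIZATION_KEY[col]
            if (tuple(t), col) in KNOWN_REALIZATION_SLIPS:
                expected = False  # consistency mapping overrides the print
            assert is_realized(t, family, setting) == expected, (t, col)


class TestCompoundOutcomes:
    def test_compound_d_reference_entries(self):
        assert compound_d(2, 6, 1, 1) == 1
        assert compound_d(2, 6, 0, 0) == 0
        assert all(compound_d(4, 16, c, cp) == 0 for c in (0, 1) for cp in (0, 1))

    def test_compound_s_selection_status(self):
        assert compound_s(1, 6, 4, 1, 1, 1) == 1
        assert compound_s(1, 6, 4, 0, 0, 0) == 0
        assert compound_s(1, 1, 16, 1, 1, 1) == 0

    def test_compound_s_has_eight_combinations(self):
        combos = {
            (c, cp, cpp)
            for c in (0, 1)
            for cp in (0, 1)
            for cpp in (0, 1)
        }
        assert len(combos) == 8
        # every combination evaluates without error on every restricted type
        for t in enumerate_types(RestrictionSet.all()):
            for c, cp, cpp in combos:
                assert compound_s(*t, c, cp, cpp) in (0, 1)


class TestConsistencyMapping:
    def test_worked_two_cell_classification(self):
        # always-exposed, confounder-driven disease, selection follows
        # disease-under-exposure: observed cell depends only on C
        assert realize_observational((1, 6, 4), 1) == (1, 1, 1)
        assert realize_observational((1, 6, 4), 0) == (1, 0, 0)

    def test_all_zero_types(self):
        assert realize_observational((4, 16, 16), 0) == (0, 0, 0)

    def test_trial_assignment_overrides_e_type(self):
        assert realize_rct(6, 4, 1, 1) == (1, 1)
        assert realize_rct(6, 4, 1, 0) == (1, 1)
        assert realize_rct(16, 16, 0, 1) == (0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        i=st.integers(1, 4),
        j=st.integers(1, 16),
        k=st.integers(1, 16),
        c=st.integers(0, 1),
    )
    def test_observational_composes_potentials(self, i, j, k, c):
        """The consistency mapping agrees with direct table lookups and with
        the trial mapping evaluated at the realized exposure."""
        e, d, s = realize_observational((i, j, k), c)
        assert e == potential("E", i, c)
        assert d == potential("D", j, c, e)
        assert s == potential("S", k, e, d)
        assert (d, s) == realize_rct(j, k, c, e)

    def test_obs_type_occupies_at_most_two_cells(self):
        for t in itertools.islice(enumerate_types(), 0, 1024, 7):
            cells = {(*realize_observational(t, c), c) for c in (0, 1)}
            assert 1 <= len(cells) <= 2

    def test_rct_pair_occupies_at_most_four_cells(self):
        worst = 0
        for j in range(1, 17):
            for k in range(1, 17):
                cells = {
                    (e, *realize_rct(j, k, c, e), c) for c in (0, 1) for e in (0, 1)
                }
                worst = max(worst, len(cells))
        assert worst == 4
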