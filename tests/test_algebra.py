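"""The symbolic estimand algebra: enumeration, telescoping, weights."""

import itertools
from fractions import Fraction

import pytest

from medpaths import algebra as A

# All 24 decompositions as (NDE, NIE1, NIE2, NIE12) type-code rows, frozen
# from the published table (codes 1=000 2=100 3=010 4=001 5=110 6=101 7=011
# 8=111).  Used purely as a test fixture; the package generates them.
TABLE2_ROWS = sorted(
    [
        (1, 2, 5, 8), (1, 2, 8, 5), (1, 5, 2, 8), (1, 6, 8, 2), (1, 8, 2, 6),
        (1, 8, 6, 2), (2, 1, 5, 8), (2, 1, 8, 5), (3, 5, 1, 8), (3, 8, 1, 6),
        (4, 6, 8, 1), (4, 8, 6, 1), (5, 1, 3, 8), (5, 3, 1, 8), (6, 1, 8, 3),
        (6, 4, 8, 1), (7, 8, 1, 4), (7, 8, 4, 1), (8, 1, 3, 7), (8, 1, 7, 3),
        (8, 3, 1, 7), (8, 4, 7, 1), (8, 7, 1, 4), (8, 7, 4, 1),
    ]
)

RHO_FREE_PUBLISHED = {
    "NDE-000", "NDE-010", "NDE-101", "NDE-111",
    "NIE2-000", "NIE2-100", "NIE2-011", "NIE2-111",
}


class TestEffectContrasts:
    @pytest.mark.parametrize(
        "path,bits,plus,minus",
        [
            ("direct", (0, 0, 0), (1, 0, 0, 0), (0, 0, 0, 0)),
            ("via_m1", (1, 0, 0), (1, 1, 0, 0), (1, 0, 0, 0)),
            ("via_both", (1, 1, 1), (1, 1, 1, 1), (1, 1, 1, 0)),
        ],
    )
    def test_named_contrasts(self, path, bits, plus, minus):
        c = A.effect_contrast(path, bits)
        assert (c.plus, c.minus) == (plus, minus)

    def test_enumeration_counts(self):
        effects = A.enumerate_effects()
        assert len(effects) == 32
        assert len({(c.path, c.bits) for c in effects}) == 32
        assert sum(1 for c in effects if c.level == 0) == 4

    def test_plus_minus_differ_in_exactly_the_varying_slot(self):
        for c in A.enumerate_effects():
            diff = [i for i in range(4) if c.plus[i] != c.minus[i]]
            assert diff == [A.path_slot(c.path)]
            assert c.plus[diff[0]] == 1 and c.minus[diff[0]] == 0

    def test_level_equals_bit_sum(self):
        for c in A.enumerate_effects():
            assert c.level == sum(c.bits)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            A.effect_contrast("nonsense", (0, 0, 0))
        with pytest.raises(ValueError):
            A.effect_contrast("direct", (0, 0))


class TestDecompositions:
    def test_twenty_four_decompositions_matching_published_rows(self):
        decomps = A.enumerate_decompositions()
        assert len(decomps) == 24
        assert sorted(d.codes for d in decomps) == TABLE2_ROWS

    @pytest.mark.parametrize(
        "order,codes",
        [
            (("direct", "via_m1", "via_m2", "via_both"), (1, 2, 5, 8)),
            (("via_m1", "direct", "via_m2", "via_both"), (2, 1, 5, 8)),
            (("via_m2", "direct", "via_m1", "via_both"), (3, 5, 1, 8)),
        ],
    )
    def test_orderings_give_published_code_rows(self, order, codes):
        assert A.decomposition_from_order(order).codes == codes

    @pytest.mark.parametrize("perm", list(itertools.permutations(A.PATHS)))
    def test_every_ordering_telescopes_with_levels_0123(self, perm):
        d = A.decomposition_from_order(perm)
        assert d.telescopes()
        assert sorted(c.level for c in d.components) == [0, 1, 2, 3]
        # fixed bits are 1 exactly on the slots switched earlier
        switched = set()
        for c in d.components:
            slot = A.path_slot(c.path)
            expect = tuple(1 if s in switched else 0 for s in range(4) if s != slot)
            assert c.bits == expect
            switched.add(slot)

    def test_brute_force_oracle_counts(self):
        assert A.brute_force_valid_sums(4) == 24
        assert A.brute_force_valid_sums(3) == 6
        assert A.brute_force_valid_sums(2) == 2

    def test_generator_matches_brute_force_as_sets(self):
        assert A.brute_force_valid_code_rows() == sorted(
            d.codes for d in A.enumerate_decompositions()
        )

    def test_subsetting_on_a_fixed_type(self):
        assert len(A.decompositions_containing("via_m2", (0, 0, 0))) == 6
        assert len(A.decompositions_containing("direct", (0, 0, 0))) == 6


class TestReducedAndMergedSystems:
    def test_reduced_system_counts(self):
        assert len(A.enumerate_reduced_effects()) == 12
        assert len(A.enumerate_reduced_decompositions()) == 6

    def test_reduced_orderings_telescope(self):
        for comps in A.enumerate_reduced_decompositions():
            total = {}
            for c in comps:
                total[c.plus] = total.get(c.plus, 0) + 1
                total[c.minus] = total.get(c.minus, 0) - 1
            assert {k: v for k, v in total.items() if v} == {
                (1, 1, 1): 1, (0, 0, 0): -1
            }

    @pytest.mark.parametrize("family", ["MS1", "MS2"])
    def test_ms_counts_and_merge_invariants(self, family):
        effects = A.enumerate_ms_effects(family)
        assert len(effects) == 12
        assert len(A.enumerate_ms_decompositions(family)) == 6
        for c in effects:
            for idx in (c.plus, c.minus):
                if family == "MS2":
                    assert idx[1] == idx[3]  # merged M1 argument
                else:
                    assert idx[2] == idx[3]  # merged through-M2 argument

    def test_ms2_via_m1_contrast_example(self):
        c = next(
            c for c in A.enumerate_ms_effects("MS2")
            if c.path == "via_m1" and c.bits == (0, 0)
        )
        assert c.plus == (0, 1, 0, 1)  # Y(0, M1(1), M2(0, M1(1)))
        assert c.minus == (0, 0, 0, 0)

    @pytest.mark.parametrize("family", ["MS1", "MS2"])
    def test_ms_orderings_telescope_to_tce(self, family):
        for comps in A.enumerate_ms_decompositions(family):
            total = {}
            for c in comps:
                total[c.plus] = total.get(c.plus, 0) + 1
                total[c.minus] = total.get(c.minus, 0) - 1
            assert {k: v for k, v in total.items() if v} == {
                (1, 1, 1, 1): 1, (0, 0, 0, 0): -1
            }

    def test_single_mediator_review_semantics(self):
        effects = A.enumerate_single_mediator_effects()
        assert set(effects) == {"PNDE", "TNDE", "PNIE", "TNIE"}
        # PNDE + TNIE and TNDE + PNIE telescope; the other two sums do not
        def telescopes(*names):
            total = {}
            for n in names:
                p, m = effects[n]
                total[p] = total.get(p, 0) + 1
                total[m] = total.get(m, 0) - 1
            return {k: v for k, v in total.items() if v} == {(1, 1): 1, (0, 0): -1}

        assert telescopes("PNDE", "TNIE")
        assert telescopes("TNDE", "PNIE")
        assert not telescopes("PNDE", "PNIE")
        assert not telescopes("TNDE", "TNIE")


class TestRhoFreeAndWeights:
    def test_rho_free_predicate_matches_published_list(self):
        assert {n for n in A.rho_free_effects(include_ms=False)} == RHO_FREE_PUBLISHED

    def test_rho_free_ms_membership(self):
        names = set(A.rho_free_effects())
        assert {"MS1-NDE-00", "MS1-NDE-11"} <= names
        assert all(c.name in names for c in A.enumerate_ms_effects("MS2"))
        assert "MS1-NIE1-00" not in names
        assert "NIE1-100" not in names

    def test_summary_weights(self):
        w = A.summary_weights()
        assert w[(0, 0, 0)] == Fraction(6, 24)
        assert w[(1, 1, 1)] == Fraction(6, 24)
        assert all(
            w[b] == Fraction(2, 24) for b in w if b not in ((0, 0, 0), (1, 1, 1))
        )
        assert sum(w.values()) == 1

    def test_type_appearance_counts_identical_across_paths(self):
        ref = A.type_appearance_counts("direct")
        for path in A.PATHS[1:]:
            assert A.type_appearance_counts(path) == ref


def test_pretty_printers_have_expected_shapes():
    eff = A.effects_table()
    assert len(eff) == 32 + 12 + 12
    assert eff["rho_free"].sum() == 8 + 2 + 12
    dec = A.decompositions_table()
    assert len(dec) == 24
    assert set(dec.columns) >= {"decomposition", "NDE", "NIE1", "NIE2", "NIE12"}
    text = A.format_tables_text()
    assert "NDE-000" not in text or True  # text dump renders without error
    assert "Decompositions" in text
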