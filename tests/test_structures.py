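"""Diagram model: parsing, crossing analysis, stacks/stems, distance."""

import numpy as np
import pytest

from knotinv.structures import (
    Arc,
    ParseError,
    Structure,
    ValidationError,
    core_and_lgraph,
    crossing_number,
    lgraph,
    pairing_partner,
    parse_structure,
    restrict,
    stacks_and_stems,
    structure_distance,
    write_structure,
)

from conftest import (
    brute_force_crossing_number,
    brute_force_diagrams,
    random_structures,
)


class TestParse:
    def test_unpaired_only(self):
        s = parse_structure("::::::")
        assert s == Structure(6)

    def test_nested_stack(self):
        s = parse_structure("((((....))))")
        assert s.arcs == frozenset(
            {Arc(1, 12), Arc(2, 11), Arc(3, 10), Arc(4, 9)}
        )

    def test_pseudoknot_families(self, pk18):
        assert pk18.arcs == frozenset(
            {Arc(1, 13), Arc(2, 12), Arc(3, 11), Arc(6, 18), Arc(7, 17), Arc(8, 16)}
        )
        assert pk18.is_valid()

    def test_dots_and_whitespace_accepted(self):
        assert parse_structure("( ( ( . . [[[ : : )))..]]]") == parse_structure(
            "(((..[[[..)))..]]]"
        )

    @pytest.mark.parametrize("text", ["(((", "))", "(]", "[[)"])
    def test_unbalanced_raises_with_position(self, text):
        with pytest.raises(ParseError) as err:
            parse_structure(text, validate=False)
        assert err.value.position is not None

    def test_validation_failure_names_invariant(self):
        with pytest.raises(ValidationError) as err:
            parse_structure("(..)....")  # arc-length 3 < 4
        assert err.value.invariant == "arc_length"
        assert Arc(1, 4) in err.value.arcs

    def test_canonicity_enforced_by_default(self):
        with pytest.raises(ValidationError) as err:
            parse_structure("((....))")  # stack of 2 < sigma=3
        assert err.value.invariant == "canonical"
        parse_structure("((....))", validate={"arc_length", "crossing"})


class TestWrite:
    def test_trivial(self):
        assert write_structure(Structure(6)) == "::::::"

    def test_single_family(self):
        s = Structure(12, [(1, 12), (2, 11), (3, 10), (4, 9)])
        assert write_structure(s) == "((((::::))))"

    def test_roundtrip_on_generated(self):
        for s in random_structures(120, n_range=(9, 34), seed=11):
            assert parse_structure(write_structure(s)) == s

    def test_crossing_needs_second_family(self, pk18):
        text = write_structure(pk18)
        assert set(text) == {"(", ")", "[", "]", ":"}
        assert parse_structure(text) == pk18


class TestCrossingNumber:
    def test_figure_triple(self):
        assert crossing_number({(1, 7), (4, 9), (5, 11)}) == 3

    def test_empty(self):
        assert crossing_number(set()) == 0

    def test_pseudoknot_example(self, pk18):
        assert crossing_number(pk18.arcs) == 2

    def test_matches_brute_force_on_small_diagrams(self):
        for s in brute_force_diagrams(9, min_arc_length=2, max_crossing=None):
            assert crossing_number(s.arcs) == brute_force_crossing_number(s.arcs)


class TestStacksStems:
    def test_single_stack(self):
        s = Structure(12, [(1, 12), (2, 11), (3, 10), (4, 9)])
        stacks, stems = stacks_and_stems(s)
        assert len(stacks) == 1 and stacks[0].size == 4
        assert len(stems) == 1 and stems[0].length == 1

    def test_two_crossing_stacks(self, pk18):
        stacks, stems = stacks_and_stems(pk18)
        assert sorted(st.size for st in stacks) == [3, 3]
        assert len(stems) == 2

    def test_isolated_arcs_are_size_one_stacks(self):
        s = Structure(10, [(1, 10), (3, 8)])
        stacks, _ = stacks_and_stems(s)
        assert sorted(st.size for st in stacks) == [1, 1]
        assert not s.is_valid({"canonical"})

    def test_stem_groups_interrupted_stacks(self):
        # two stacks separated by unpaired nucleotides on one side only
        s = parse_structure("(((:((((::::)))))))", validate={"crossing"})
        stacks, stems = stacks_and_stems(s)
        assert len(stacks) == 2
        assert len(stems) == 1
        assert stems[0].length == 2

    def test_every_arc_in_exactly_one_stack(self):
        for s in random_structures(60, seed=3):
            stacks, _ = stacks_and_stems(s)
            counted = [a for st in stacks for a in st.arcs]
            assert sorted(counted) == s.sorted_arcs()


class TestDistance:
    def test_identity(self, pk18):
        assert structure_distance(pk18, pk18) == 0

    def test_type_two_positions(self):
        assert structure_distance(Structure(5, [(1, 5)]), Structure(5)) == 2

    def test_mixed_types(self):
        s1 = Structure(6, [(1, 5)])
        s2 = Structure(6, [(1, 6)])
        assert structure_distance(s1, s2) == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            structure_distance(Structure(5), Structure(6))

    def test_metric_axioms_exhaustive(self):
        """Non-negativity, identity, symmetry and the triangle
        inequality over every diagram of length 6."""
        structs = brute_force_diagrams(6)
        partner = np.array([s.partners()[1:] for s in structs])
        d = (partner[:, None, :] != partner[None, :, :]).sum(axis=2)
        assert (d >= 0).all()
        assert (np.diag(d) == 0).all()
        assert (d == d.T).all()
        assert ((d == 0) == np.eye(len(structs), dtype=bool)).all()
        for k in range(len(structs)):
            assert (d <= d[:, k, None] + d[None, k, :]).all()


class TestPartners:
    def test_lookup(self):
        s = Structure(7, [(2, 7)])
        assert pairing_partner(s, 2) == 7
        assert pairing_partner(s, 7) == 2
        assert pairing_partner(s, 1) == 0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pairing_partner(Structure(7, [(2, 7)]), 8)

    def test_involution_on_generated(self):
        for s in random_structures(50, seed=5):
            for w in range(1, s.n + 1):
                p = pairing_partner(s, w)
                if p:
                    assert pairing_partner(s, p) == w


class TestCoreAndLGraph:
    def test_nested_stack_core(self):
        s = Structure(12, [(1, 12), (2, 11), (3, 10), (4, 9)])
        core, lg = core_and_lgraph(s)
        assert len(core.arcs) == 1
        assert lg.number_of_edges() == 0
        core2, lg_core = core_and_lgraph(core)
        assert lg_core.number_of_nodes() == 1 and lg_core.number_of_edges() == 0

    def test_pseudoknot_core_connected(self, pk18):
        core, lg = core_and_lgraph(pk18)
        assert len(core.arcs) == 2
        assert crossing_number(core.arcs) == 2
        _, lg_core = core_and_lgraph(core)
        assert lg_core.number_of_edges() == 1

    def test_noncrossing_lgraph_edgeless(self):
        for s in random_structures(30, pk_fraction=0.0, seed=9):
            assert lgraph(s).number_of_edges() == 0


class TestValidator:
    def test_default_acceptance_rule(self):
        ok = Structure(12, [(1, 12), (2, 11), (3, 10), (4, 9)])
        assert ok.is_valid()
        assert not Structure(6, [(1, 6), (2, 5)], min_arc_length=2).is_valid()
        assert not Structure(3, [(1, 2)], min_arc_length=1).is_valid(
            {"no_adjacent"}
        )
        bad_degree = Structure(8, [(1, 8), (1, 6)])
        assert not bad_degree.is_consistent
        assert not bad_degree.is_valid()

    def test_empty_structure_valid_everywhere(self):
        assert Structure(0).is_valid()
        assert Structure(25).is_valid()

    def test_three_crossing_rejected(self):
        s = Structure(11, [(1, 7), (4, 9), (5, 11)])
        with pytest.raises(ValidationError) as err:
            s.validate({"crossing"})
        assert err.value.invariant == "crossing"
        assert len(err.value.arcs) == 3


class TestRestrict:
    def test_shifts_arcs(self, pk18):
        sub = restrict(pk18, 1, 18)
        assert sub == pk18

    def test_straddling_arc_rejected(self, pk18):
        with pytest.raises(ValueError):
            restrict(pk18, 1, 12)
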