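"""The search: perturbation, competitors, mutation, end-to-end design."""

import itertools
import random

import pytest

from knotinv.folding import EnergyModel, ReferenceOracle, get_oracle
from knotinv.inverse import (
    CompetitorSet,
    SearchConfig,
    adjust_seq,
    build_competitors,
    inverse_fold,
    local_search,
    mutate_sequence,
    perturb_arc,
)
from knotinv.loops import interval_sequence
from knotinv.seqspace import ALLOWED_PAIRS, can_pair, is_compatible, make_start
from knotinv.structures import (
    Arc,
    Structure,
    parse_structure,
    structure_distance,
)


class TestPerturbArc:
    def test_interior_arc_yields_ten(self):
        s = Structure(12, [(3, 9)])
        out = perturb_arc(s, Arc(3, 9))
        assert len(out) == 10
        placements = [p for p in out if len(p.arcs) == 1]
        removals = [p for p in out if len(p.arcs) == 0]
        assert len(placements) == 9 and len(removals) == 1
        assert s in out  # the unperturbed structure is kept

    def test_boundary_clipping(self):
        s = Structure(5, [(1, 5)])
        out = perturb_arc(s, Arc(1, 5))
        assert len(out) == 5  # 2x2 placements + removal

    def test_removal_always_present(self, pk18):
        for a in pk18.arcs:
            out = perturb_arc(pk18, a)
            assert any(len(p.arcs) == len(pk18.arcs) - 1 for p in out)

    def test_unknown_arc_rejected(self, pk18):
        with pytest.raises(ValueError):
            perturb_arc(pk18, Arc(1, 5))


class TestCompetitors:
    def test_inconsistent_structures_excluded(self):
        # perturbing (3, 9) next to (10, 15) can move an endpoint onto 10
        s = Structure(15, [(3, 9), (10, 15)])
        comp = build_competitors([s], "GAAAAAACGAAAAAC", Structure(15))
        assert all(p.is_consistent for p in comp)

    def test_incompatible_structures_excluded(self):
        seq = "GAAAC" + "A" * 5  # only (1, 5) can pair
        s = Structure(10, [(1, 5)])
        comp = build_competitors([s], seq, Structure(10, [(2, 6)]))
        for p in comp:
            assert is_compatible(seq, p)

    def test_target_excluded(self, pk18):
        seq = make_start(pk18, random.Random(0))
        comp = build_competitors([pk18], seq, pk18)
        assert pk18 not in comp.members

    def test_bounded_by_ten_per_arc(self):
        s = Structure(20, [(2, 10), (12, 19)])
        seq = "G" * 10 + "C" * 10
        comp = build_competitors([s], seq, Structure(20))
        assert len(comp) <= 10 * len(s.arcs)

    def test_provenance_recorded(self):
        s = Structure(12, [(3, 9)])
        comp = build_competitors([s], "AAGAAAAACAAA", Structure(12))
        for member in comp:
            h, arc = comp.provenance[member]
            assert h == 0 and arc == Arc(3, 9)


class TestMutation:
    def test_no_conflict_returns_unchanged(self, rng):
        T = Structure(10, [(2, 8)])
        seq = "AGAAAAACAA"
        comp = CompetitorSet((Structure(10, [(2, 8)]),))  # agrees with T
        assert mutate_sequence(seq, T, comp, rng) == seq

    def test_breaks_shifted_competitor_pair(self):
        """Target pairs (5, 9), a competitor pairs (5, 10): the redrawn
        pair at (5, 9) must break the competitor while staying
        target-compatible."""
        T = Structure(10, [(5, 9)])
        competitor = Structure(10, [(5, 10)])
        seq = "AAAAGAAACU"  # G-C on (5,9); G-U possible on (5,10)
        assert is_compatible(seq, T) and is_compatible(seq, competitor)
        hits = 0
        for trial in range(20):
            out = mutate_sequence(
                seq, T, CompetitorSet((competitor,)), random.Random(trial)
            )
            assert is_compatible(out, T)
            assert (out[4], out[8]) != (seq[4], seq[8])
            if not is_compatible(out, competitor):
                hits += 1
        assert hits == 20  # a fully breaking pair exists here

    def test_unpaired_position_breaks_competitor(self):
        T = Structure(8)
        competitor = Structure(8, [(2, 7)])
        seq = "AAAAAAUA"  # A-U possible at (2,7)
        out = mutate_sequence(
            seq, T, CompetitorSet((competitor,)), random.Random(1)
        )
        assert not can_pair(out[1], out[6])

    def test_breaking_choice_characterization(self):
        """Enumeration over the six-pair table: a fully
        competitor-breaking target-compatible pair exists for every
        combination of at most two distinct competitor partner bases,
        except when those bases are exactly {G, U} -- every base can
        pair with G or with U, so only the most-breaking fallback
        applies there."""
        bases = "ACGU"
        for cur in ALLOWED_PAIRS:
            for b1, b2 in itertools.combinations_with_replacement(bases, 2):
                options = [
                    p
                    for p in ALLOWED_PAIRS
                    if p != cur
                    and not can_pair(p[0], b1)
                    and not can_pair(p[0], b2)
                ]
                if {b1, b2} == {"G", "U"}:
                    assert not options
                else:
                    cur_breaks = not can_pair(cur[0], b1) and not can_pair(
                        cur[0], b2
                    )
                    assert options or cur_breaks, (cur, b1, b2)

    def test_result_compatible_with_target(self, pk18, rng):
        seq = make_start(pk18, rng)
        oracle = get_oracle()
        comp = build_competitors(oracle(seq, 10), seq, pk18)
        for _ in range(10):
            seq = mutate_sequence(seq, pk18, comp, rng)
            assert is_compatible(seq, pk18)


class TestAdjustSeq:
    def test_immediate_hit_returns_start(self):
        T = Structure(12, [(1, 12), (2, 11), (3, 10), (4, 9)])
        start = "GGGGAAAACCCC"  # already folds to T
        out = adjust_seq(start, T, SearchConfig(seed=0), get_oracle())
        assert out == start

    def test_output_compatible(self, pk18):
        rng = random.Random(3)
        start = make_start(pk18, rng)
        out = adjust_seq(start, pk18, SearchConfig(seed=3), get_oracle(), rng)
        assert is_compatible(out, pk18)

    def test_incompatible_start_rejected(self, hairpin12):
        with pytest.raises(ValueError):
            adjust_seq("A" * 12, hairpin12, SearchConfig(), get_oracle())


class TestLocalSearch:
    def test_already_solved_returned_unchanged(self):
        T = Structure(12, [(1, 12), (2, 11), (3, 10), (4, 9)])
        seq = "GGGGAAAACCCC"
        out = local_search(
            seq, T, interval_sequence(T), SearchConfig(seed=0), get_oracle()
        )
        assert out == seq

    def test_output_compatible(self, pk18):
        rng = random.Random(5)
        seq = make_start(pk18, rng)
        out = local_search(
            seq, pk18, interval_sequence(pk18), SearchConfig(seed=5),
            get_oracle(), rng,
        )
        assert is_compatible(out, pk18)

    def test_pure_hill_climb_never_worsens(self, pk18):
        """With p_accept = 0 the per-interval distance trajectory is
        non-increasing: the final distance cannot exceed the start."""
        oracle = get_oracle()
        rng = random.Random(7)
        seq = make_start(pk18, rng)
        d0 = structure_distance(oracle(seq, 1).mfe, pk18)
        cfg = SearchConfig(p_accept=0.0, seed=7)
        out = local_search(seq, pk18, interval_sequence(pk18), cfg, oracle, rng)
        d1 = structure_distance(oracle(out, 1).mfe, pk18)
        assert d1 <= d0


class TestInverseFold:
    def test_empty_target(self):
        r = inverse_fold(Structure(8), SearchConfig(seed=0))
        assert r.success
        assert r.mfe == Structure(8)

    def test_hairpin_target(self):
        T = parse_structure("((((....))))")
        r = inverse_fold(T, SearchConfig(seed=1))
        assert r.success
        assert get_oracle()(r.sequence, 1).mfe == T

    def test_pseudoknot_target_with_cheap_knots(self):
        """The pseudoknot design path: with a lowered knot penalty the
        search finds a sequence folding into the knot."""
        T = parse_structure("(((..[[[..)))..]]]")
        oracle = ReferenceOracle(EnergyModel(pseudoknot=2.0))
        r = inverse_fold(T, SearchConfig(seed=2), oracle)
        assert r.success
        assert oracle(r.sequence, 1).mfe == T

    def test_pseudoknot_target_default_model(self):
        T = parse_structure("(((..[[[..)))..]]]")
        r = inverse_fold(T, SearchConfig(seed=1))
        assert r.success

    def test_invalid_target_rejected(self):
        bad = Structure(11, [(1, 7), (4, 9), (5, 11)])  # 3-crossing
        with pytest.raises(Exception):
            inverse_fold(bad)

    def test_failure_reports_best_distance(self):
        """An unreachable target (knot priced out of the market) yields
        a failure result carrying the residual distance."""
        T = parse_structure("(((..[[[..)))..]]]")
        oracle = ReferenceOracle(EnergyModel(pseudoknot=100.0))
        cfg = SearchConfig(seed=3, adjust_iters=5, phase_max_factor=1)
        r = inverse_fold(T, cfg, oracle)
        assert not r.success
        assert r.distance > 0
        assert is_compatible(r.sequence, T)

    def test_reproducible(self):
        T = parse_structure("(((..[[[..)))..]]]")
        a = inverse_fold(T, SearchConfig(seed=11))
        b = inverse_fold(T, SearchConfig(seed=11))
        assert a.sequence == b.sequence
        assert a.success == b.success
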