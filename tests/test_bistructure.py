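"""Structure parsing, loop decomposition and the substructure algebra."""

import pytest
from hypothesis import given, strategies as st

from bicompat.bistructure_core import (
    SecondaryStructure,
    StructureError,
    build_bistructure,
    is_bicompatible,
    parse_dotbracket,
    substructure_algebra,
)
from bicompat.oracle_fixtures import (
    count_bicompatible_walks,
    random_bistructure,
    raw_scan_count,
)

WEX_LOOP_SETS = {
    frozenset({0, 1, 4, 5, 7, 8, 9}),
    frozenset({1, 2, 3, 4}),
    frozenset({2, 3}),
    frozenset({5, 6, 7}),
    frozenset({0, 1, 2, 3, 4, 5, 6, 8, 9}),
    frozenset({6, 7, 8}),
}


class TestParse:
    @pytest.mark.parametrize(
        "text,arcs",
        [
            ("(())(.).", {(1, 4), (2, 3), (5, 7)}),
            ("........", set()),
            ("(...)", {(1, 5)}),
        ],
    )
    def test_matched_pairs(self, text, arcs):
        assert parse_dotbracket(text, min_hairpin=0).arcs == frozenset(arcs)

    @pytest.mark.parametrize("bad", ["(()", "())", "(.[.)]", "(A)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(StructureError):
            parse_dotbracket(bad, min_hairpin=0)

    def test_short_hairpin_rejected_when_enforced(self):
        with pytest.raises(StructureError):
            parse_dotbracket("(.)", min_hairpin=3)
        assert parse_dotbracket("(...)", min_hairpin=3).arcs == frozenset({(1, 5)})


class TestLoops:
    def test_worked_example_vertex_sets(self, wex):
        assert {lp.vertices for lp in wex.loops} == WEX_LOOP_SETS
        assert len(wex.loops) == 6

    def test_both_rainbows_only(self):
        empty = SecondaryStructure(4, frozenset(), min_hairpin=0)
        B = build_bistructure(empty, empty)
        assert len(B.loops) == 2
        assert all(lp.vertices == frozenset(range(6)) for lp in B.loops)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            build_bistructure(
                SecondaryStructure(4, frozenset(), 0),
                SecondaryStructure(5, frozenset(), 0),
            )

    def test_loop_count_and_arc_multiplicity(self, random_suite):
        """Every non-rainbow arc sits in exactly two loops of its layer,
        maximal in exactly one; loop count = arcs + 2; vertices covered."""
        for B in random_suite:
            n_arcs = len(B.structure_R.arcs) + len(B.structure_S.arcs)
            assert len(B.loops) == n_arcs + 2
            union = set()
            for lp in B.loops:
                union |= lp.vertices
            assert union == set(range(B.n + 2))
            for arc in B.nonrainbow_arcs:
                holders = [
                    lp
                    for lp in B.loops
                    if lp.layer == arc.layer
                    and any(a.span == arc.span for a in lp.arcs)
                ]
                assert len(holders) == 2
                assert sum(lp.maximal_arc.span == arc.span for lp in holders) == 1


class TestSubstructureAlgebra:
    def _by_vertices(self, B, verts):
        return next(lp.id for lp in B.loops if lp.vertices == frozenset(verts))

    def test_worked_example_inner_pair(self, wex):
        e2 = self._by_vertices(wex, {1, 2, 3, 4})
        e3 = self._by_vertices(wex, {2, 3})
        e1 = self._by_vertices(wex, {0, 1, 4, 5, 7, 8, 9})
        e5 = self._by_vertices(wex, {0, 1, 2, 3, 4, 5, 6, 8, 9})
        X = wex.substructure([e2, e3])
        exposed, boundary, closure, comps = substructure_algebra(X)
        assert exposed == frozenset({1, 2, 3, 4})
        assert boundary.loop_ids == frozenset({e1, e5})
        assert closure.loop_ids == frozenset({e1, e2, e3, e5})
        assert len(comps) == 1

    def test_full_substructure_has_no_exposed_vertices(self, wex):
        assert wex.full_substructure().exposed == frozenset()

    def test_disjoint_loops_split_into_components(self, wex):
        e2 = self._by_vertices(wex, {1, 2, 3, 4})
        e4 = self._by_vertices(wex, {5, 6, 7})
        comps = wex.substructure([e2, e4]).components()
        assert sorted(c.loop_ids for c in comps) == sorted(
            [frozenset({e2}), frozenset({e4})]
        )

    def test_empty_substructure_rejected(self, wex):
        with pytest.raises(ValueError):
            substructure_algebra(wex.substructure([]))

    def test_exposed_symmetry_and_closure_growth(self, random_suite):
        """E^X == E^{X-bar}; the closure contains X; irreducible parts
        partition the loop set."""
        for B in random_suite[:50]:
            ids = sorted(lp.id for lp in B.loops)
            X = B.substructure(ids[: max(1, len(ids) // 2)])
            assert X.exposed == X.complement.exposed
            assert X.closure.loop_ids >= X.loop_ids
            comps = X.components()
            assert frozenset().union(*(c.loop_ids for c in comps)) == X.loop_ids
            for c in comps:
                assert c.is_irreducible


class TestBicompatibility:
    def test_worked_example_sequences(self, wex):
        assert is_bicompatible("GCGCAGUC", wex)
        assert not is_bicompatible("AAAAAAAA", wex)

    def test_arc_free_accepts_everything(self):
        empty = SecondaryStructure(6, frozenset(), 0)
        B = build_bistructure(empty, empty)
        assert is_bicompatible("ACGUAC", B)

    def test_bad_input_rejected(self, wex):
        with pytest.raises(ValueError):
            is_bicompatible("ACGU", wex)
        with pytest.raises(ValueError):
            is_bicompatible("ACGUACGX", wex)

    @pytest.mark.parametrize("seed", range(20))
    def test_walk_count_equals_raw_scan(self, seed):
        """Component walk-count product equals the literal 4^n scan (n <= 8)."""
        B = random_bistructure(n=4 + seed % 5, seed=seed)
        assert count_bicompatible_walks(B) == raw_scan_count(B)


@given(st.integers(4, 30), st.integers(0, 10**6))
def test_dotbracket_round_trip(n, seed):
    """write -> parse reproduces arcs for random structures."""
    B = random_bistructure(n=n, seed=seed)
    R = B.structure_R
    assert parse_dotbracket(R.to_dotbracket(), min_hairpin=0).arcs == R.arcs
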