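"""Hypergeometric testing, Holm correction, kappa and term grouping."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    components_by_union_find,
    holm_by_definition,
    hypergeom_tails_by_draws,
    hypergeom_two_sided_exact,
    kappa_from_vectors,
)

from hubnet import (
    EnrichmentConfig,
    GeneSet,
    SyntheticSpec,
    ValidationError,
    bonferroni_step_down,
    generate_annotations,
    group_terms,
    hypergeometric_two_sided,
    kappa_score,
    run_enrichment,
)


def _term(tid, genes, depth=None):
    return GeneSet(term_id=tid, term_name=tid, genes=frozenset(genes), depth=depth)


class TestHypergeometric:
    def test_full_overlap_doubled_tail(self):
        direction, p = hypergeometric_two_sided(5, 5, 5, 10)
        assert direction == "enriched"
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_degenerate_term(self):
        assert hypergeometric_two_sided(0, 0, 5, 10)[1] == 1.0

    def test_against_exact_enumeration(self):
        direction, p = hypergeometric_two_sided(2, 4, 5, 10)
        d_exact, p_exact = hypergeom_two_sided_exact(2, 4, 5, 10)
        assert direction == d_exact
        assert p == pytest.approx(float(p_exact), abs=1e-12)

    def test_against_literal_draws(self):
        """Tails agree with counting every size-n draw of a tiny universe."""
        for k, K, n, N in [(2, 3, 4, 8), (0, 3, 3, 7), (3, 3, 3, 6), (1, 4, 2, 9)]:
            upper, lower = hypergeom_tails_by_draws(k, K, n, N)
            _, p = hypergeometric_two_sided(k, K, n, N)
            assert p == pytest.approx(float(min(1, 2 * min(upper, lower))), abs=1e-12)

    def test_depletion_direction(self):
        direction, _ = hypergeometric_two_sided(0, 6, 6, 12)
        assert direction == "depleted"

    def test_bound_violations(self):
        for bad in [(6, 5, 5, 10), (1, 11, 5, 10), (0, 2, 5, 6)]:
            with pytest.raises(ValidationError):
                hypergeometric_two_sided(*bad)


class TestHolm:
    def test_singleton_identity(self):
        assert bonferroni_step_down([0.04]) == [0.04]

    def test_worked_example(self):
        assert bonferroni_step_down([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_empty(self):
        assert bonferroni_step_down([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_step_down([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_definition_and_bounds(self, ps):
        out = bonferroni_step_down(ps)
        oracle = holm_by_definition(ps)
        m = len(ps)
        for got, want, raw in zip(out, oracle, ps):
            assert got == pytest.approx(want, abs=1e-12)
            assert raw - 1e-12 <= got <= min(1.0, raw * m) + 1e-12

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, ps, rng):
        perm = list(range(len(ps)))
        rng.shuffle(perm)
        shuffled = [ps[i] for i in perm]
        base = bonferroni_step_down(ps)
        back = bonferroni_step_down(shuffled)
        for i, j in enumerate(perm):
            assert back[i] == pytest.approx(base[j], abs=1e-12)


class TestKappa:
    UNIVERSE = [f"G{i}" for i in range(20)]

    def test_identical_terms(self):
        t = _term("A", self.UNIVERSE[:10])
        assert kappa_score(t, t, self.UNIVERSE) == 1.0

    def test_worked_example(self):
        a = _term("A", self.UNIVERSE[:10])
        b = _term("B", self.UNIVERSE[2:12])  # |A∩B| = 8
        assert kappa_score(a, b, self.UNIVERSE) == pytest.approx(0.6)

    def test_complementary_halves(self):
        a = _term("A", self.UNIVERSE[:10])
        b = _term("B", self.UNIVERSE[10:])
        assert kappa_score(a, b, self.UNIVERSE) == pytest.approx(-1.0)

    def test_empty_universe_rejected(self):
        a = _term("A", ["G1"])
        with pytest.raises(ValidationError):
            kappa_score(a, a, [])

    @given(
        mask_a=st.lists(st.booleans(), min_size=4, max_size=16),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_confusion_matrix_oracle_and_symmetry(self, mask_a, data):
        n = len(mask_a)
        mask_b = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(mask_a) and any(mask_b)):
            return
        uni = [f"G{i}" for i in range(n)]
        a = _term("A", [g for g, m in zip(uni, mask_a) if m])
        b = _term("B", [g for g, m in zip(uni, mask_b) if m])
        got = kappa_score(a, b, uni)
        assert got == pytest.approx(
            kappa_from_vectors([int(m) for m in mask_a], [int(m) for m in mask_b]),
            abs=1e-12,
        )
        assert got == pytest.approx(kappa_score(b, a, uni), abs=1e-12)


class TestRunEnrichment:
    def test_planted_term_has_smallest_corrected_p(self):
        """Seeded construction: 5 of 15 query genes inside a 25-gene term of
        a 500-gene universe, against 49 null decoys."""
        universe = {f"G{i:04d}" for i in range(500)}
        query = frozenset(sorted(universe)[:15])
        spec = SyntheticSpec(seed=13, n_terms=50, n_planted_terms=1,
                             planted_overlap=5, term_size_range=(25, 25))
        terms = generate_annotations(universe, spec, query)
        results = run_enrichment(query, terms, universe)
        best = min(results, key=lambda r: (r.p_corrected, r.term.term_id))
        assert best.term.term_id == "PLANTED1"
        assert best.k == 5 and best.direction == "enriched"

    def test_min_genes_filter(self):
        universe = {f"G{i}" for i in range(40)}
        terms = [_term("T1", list(sorted(universe))[:4])]
        query = set(sorted(universe)[:2]) | {sorted(universe)[30]}
        results = run_enrichment(query, terms, universe)
        assert results[0].k == 2 and not results[0].passes_filters

    def test_depth_window(self):
        universe = [f"G{i}" for i in range(30)]
        query = universe[:6]
        terms = [
            _term("SHALLOW", universe[:6], depth=1),
            _term("IN_WINDOW", universe[:6], depth=5),
            _term("NO_DEPTH", universe[:6]),
        ]
        by_id = {r.term.term_id: r for r in run_enrichment(query, terms, universe)}
        assert not by_id["SHALLOW"].passes_filters
        assert by_id["IN_WINDOW"].passes_filters
        assert by_id["NO_DEPTH"].passes_filters  # depth unknown: never level-filtered

    def test_out_of_universe_query_dropped(self):
        universe = [f"G{i}" for i in range(10)]
        terms = [_term("T1", universe[:5])]
        results = run_enrichment(universe[:3] + ["ALIEN"], terms, universe)
        assert results[0].n == 3

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            run_enrichment(["ALIEN"], [_term("T1", ["G1"])], ["G1", "G2"])


class TestGroupTerms:
    def test_shared_genes_one_group(self):
        genes = [f"G{i}" for i in range(12)]
        terms = [_term("A", genes[:6]), _term("B", genes[:6])]
        results = run_enrichment(genes[:4], terms, genes, EnrichmentConfig(alpha=1.0,
                                 min_genes=0, min_pct=0))
        groups = group_terms(results, 0.5)
        assert len(groups) == 1 and groups[0].members == {"A", "B"}
        assert groups[0].leading_term in {"A", "B"}

    def test_disjoint_terms_singletons(self):
        genes = [f"G{i}" for i in range(12)]
        terms = [_term("A", genes[:4]), _term("B", genes[4:8]), _term("C", genes[8:])]
        results = run_enrichment(genes[:4], terms, genes,
                                 EnrichmentConfig(alpha=1.0, min_genes=0, min_pct=0))
        groups = group_terms(results, 0.5)
        assert sorted(len(g.members) for g in groups) == [1, 1, 1]

    def test_components_match_union_find_oracle(self):
        """Five constructed terms: kappa graph components equal union-find."""
        import numpy as np

        rng = np.random.default_rng(17)
        genes = [f"G{i}" for i in range(40)]
        terms = [
            _term(f"T{j}", [genes[int(i)] for i in rng.choice(40, 12, replace=False)])
            for j in range(5)
        ]
        results = run_enrichment(genes[:8], terms, genes,
                                 EnrichmentConfig(alpha=1.0, min_genes=0, min_pct=0))
        threshold = 0.2
        groups = group_terms(results, threshold)
        passing = [r.term for r in results if r.passes_filters]
        universe = frozenset().union(*(t.genes for t in passing))
        edges = [
            (a.term_id, b.term_id)
            for a, b in itertools.combinations(passing, 2)
            if kappa_score(a, b, universe) >= threshold
        ]
        oracle = components_by_union_find([t.term_id for t in passing], edges)
        assert {g.members for g in groups} == oracle

    def test_order_independence(self):
        genes = [f"G{i}" for i in range(20)]
        terms = [_term("A", genes[:8]), _term("B", genes[2:10]), _term("C", genes[12:])]
        cfg = EnrichmentConfig(alpha=1.0, min_genes=0, min_pct=0)
        g1 = group_terms(run_enrichment(genes[:5], terms, genes, cfg), 0.3)
        g2 = group_terms(run_enrichment(genes[:5], terms[::-1], genes, cfg), 0.3)
        assert {g.members for g in g1} == {g.members for g in g2}
        assert [g.leading_term for g in g1] == [g.leading_term for g in g2]

    def test_no_passing_terms(self):
        assert group_terms([], 0.5) == []
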