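"""Hypergeometric enrichment: exact-tail oracle, universe semantics, pathway network."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from comorbnet import GeneSetCollection, MirnaTables, build_pathway_network, enrich, enrich_mirna, hypergeom_upper_tail
from comorbnet.datatypes import GeneSet
from comorbnet.errors import DomainError, UnknownEntityError

from .oracles import hypergeom_tail_by_enumeration


class TestUpperTail:
    def test_k_zero_is_certain(self):
        for K, n, N in [(3, 4, 10), (0, 5, 5), (7, 2, 9)]:
            assert hypergeom_upper_tail(0, K, n, N) == 1.0

    def test_full_draw_forces_overlap(self):
        # n = N draws the whole universe: overlap is K with certainty
        assert hypergeom_upper_tail(4, 4, 10, 10) == 1.0

    def test_worked_value_4_of_4_in_5_from_10(self):
        p = hypergeom_upper_tail(4, 4, 5, 10)
        assert p == pytest.approx(6 / 252, abs=1e-12)
        assert p == pytest.approx(float(hypergeom_tail_by_enumeration(4, 4, 5, 10)), abs=1e-12)

    @pytest.mark.parametrize(
        "k,K,n,N",
        [
            (-1, 2, 2, 4),  # k below zero
            (3, 2, 5, 6),   # k above min(K, n)
            (1, 7, 2, 6),   # K above N
            (0, 2, 7, 6),   # n above N
            (0, 4, 4, 6),   # k below the support floor max(0, n+K-N) = 2
        ],
    )
    def test_out_of_range_parameters_raise(self, k, K, n, N):
        with pytest.raises(DomainError):
            hypergeom_upper_tail(k, K, n, N)

    def test_matches_enumeration_on_a_small_grid(self):
        for N in (5, 7, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        exact = hypergeom_tail_by_enumeration(k, K, n, N)
                        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                            float(exact), abs=1e-12
                        )

    @given(st.data())
    def test_complement_identity(self, data):
        # P(X >= k) + P(X <= k-1) = 1, with the lower tail rewritten as an
        # upper tail of the complementary count n - X ~ Hypergeom(N, N-K, n)
        N = data.draw(st.integers(1, 40))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(K, n)))
        upper = hypergeom_upper_tail(k, K, n, N)
        lower = (
            hypergeom_upper_tail(n - k + 1, N - K, n, N)
            if n - k + 1 <= min(N - K, n)
            else 0.0
        )
        assert upper + lower == pytest.approx(1.0, abs=1e-12)


def _pathways(mapping, universe=None):
    return GeneSetCollection(
        [GeneSet(sid, "", frozenset(gs)) for sid, gs in mapping.items()], universe=universe
    )


class TestEnrich:
    def test_query_equals_pathway_equals_universe(self):
        pw = _pathways({"P1": {"g1", "g2", "g3"}})
        rows = enrich({"g1", "g2", "g3"}, pw)
        (r,) = rows
        assert (r.k, r.K, r.n, r.N) == (3, 3, 3, 3)
        assert r.p_value == 1.0

    def test_disjoint_query_yields_no_rows(self):
        pw = _pathways({"P1": {"g1"}})
        assert enrich({"zz"}, pw) == []

    def test_planted_four_of_five_enriched_at_gene_alpha_only(self):
        universe = {f"g{i}" for i in range(10)}
        pw = _pathways({"P1": {"g0", "g1", "g2", "g3"}}, universe=universe)
        query = {"g0", "g1", "g2", "g3", "g9"}
        (row,) = enrich(query, pw, alpha=0.05)
        assert row.p_value == pytest.approx(6 / 252, abs=1e-12)
        assert row.enriched
        (row_strict,) = enrich(query, pw, alpha=0.001)
        assert not row_strict.enriched

    def test_invariant_to_out_of_universe_query_genes(self):
        universe = {f"g{i}" for i in range(8)}
        pw = _pathways({"P1": {"g0", "g1", "g2"}, "P2": {"g3", "g4"}}, universe=universe)
        base = enrich({"g0", "g1", "g3"}, pw)
        noisy = enrich({"g0", "g1", "g3", "outside1", "outside2"}, pw)
        assert base == noisy

    def test_rows_sorted_by_p_then_id(self, small_universe):
        u = small_universe
        query = u.gene_disease.genes_of("D_ENR")
        rows = enrich(query, u.pathways)
        keys = [(r.p_value, r.set_id) for r in rows]
        assert keys == sorted(keys)
        assert rows[0].set_id == "PW_PLANTED"

    def test_fdr_flag_monotone(self, small_universe):
        u = small_universe
        rows_raw = enrich(u.gene_disease.genes_of("D_ENR"), u.pathways, alpha=0.05)
        rows_fdr = enrich(u.gene_disease.genes_of("D_ENR"), u.pathways, alpha=0.05, fdr=True)
        # BH q-values are >= raw p-values, so FDR flags a subset
        assert {r.set_id for r in rows_fdr if r.enriched} <= {r.set_id for r in rows_raw if r.enriched}
        assert all(r.q_value is not None and r.q_value >= r.p_value - 1e-15 for r in rows_fdr)


class TestEnrichMirna:
    def _mir(self, disease_mirnas, mirna_targets):
        return MirnaTables(
            disease_mirnas={d: frozenset(v) for d, v in disease_mirnas.items()},
            mirna_targets={m: frozenset(v) for m, v in mirna_targets.items()},
        )

    def test_single_mirna_covering_one_pathway_ranks_it_first(self):
        pw = _pathways({"P1": {"g0", "g1", "g2"}, "P2": {"g5", "g6", "g7", "g8"}})
        mir = self._mir({"D": {"m1"}}, {"m1": {"g0", "g1", "g2"}})
        rows = enrich_mirna("D", mir, pw)
        assert rows[0].set_id == "P1"

    def test_duplicate_target_sets_are_union_idempotent(self):
        pw = _pathways({"P1": {"g0", "g1"}, "P2": {"g2", "g3"}})
        one = self._mir({"D": {"m1"}}, {"m1": {"g0", "g1"}})
        two = self._mir({"D": {"m1", "m2"}}, {"m1": {"g0", "g1"}, "m2": {"g0", "g1"}})
        assert enrich_mirna("D", one, pw) == enrich_mirna("D", two, pw)

    def test_disease_without_mirnas_raises(self):
        pw = _pathways({"P1": {"g0"}})
        mir = self._mir({"D": {"m1"}}, {"m1": {"g0"}})
        with pytest.raises(UnknownEntityError):
            enrich_mirna("NOPE", mir, pw)

    def test_planted_mirna_enrichment_flagged_at_strict_alpha(self, small_universe):
        u = small_universe
        rows = enrich_mirna("D_ENR", u.mirna, u.pathways, alpha=0.001)
        flagged = {r.set_id for r in rows if r.enriched}
        assert "PW_PLANTED" in flagged


class TestPathwayNetwork:
    def test_shared_genes_become_weighted_edge(self):
        pw = _pathways({"P1": {"a", "b", "c", "d"}, "P2": {"b", "c", "d", "e"}})
        rows = enrich({"a", "b", "c", "d", "e"}, pw, alpha=1.0)
        g = build_pathway_network(rows, pw)
        assert g.edges["P1", "P2"]["weight"] == 3

    def test_disjoint_pathways_give_edgeless_network(self):
        pw = _pathways({"P1": {"a"}, "P2": {"b"}})
        rows = enrich({"a", "b"}, pw, alpha=1.0)
        g = build_pathway_network(rows, pw)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"P1", "P2"}

    def test_chained_overlaps_match_pairwise_intersection_oracle(self):
        sets = {"P1": {"a", "b"}, "P2": {"b", "c"}, "P3": {"c", "d"}}
        pw = _pathways(sets)
        rows = enrich({"a", "b", "c", "d"}, pw, alpha=1.0)
        g = build_pathway_network(rows, pw)
        for x in sets:
            for y in sets:
                if x >= y:
                    continue
                shared = sets[x] & sets[y]
                if shared:
                    assert g.edges[x, y]["weight"] == len(shared)
                else:
                    assert not g.has_edge(x, y)
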