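"""The four comorbidity scores: worked examples, symmetry, ranges, separation conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from comorbnet import (
    GeneDiseaseTable,
    GeneSetCollection,
    Interactome,
    comorbidity_matrix,
    gene_uniqueness,
    score_network_separation,
    score_ontology,
    score_shared_genes,
    score_uniqueness,
)
from comorbnet.datatypes import GeneSet
from comorbnet.errors import ConfigurationError, UndefinedScoreError, UnknownEntityError

from .oracles import separation_score


def _gd(mapping, n_total=None):
    records = [(d, d, g) for d, genes in mapping.items() for g in genes]
    if n_total is not None:
        for i in range(n_total - len(mapping)):
            records.append((f"PAD{i}", f"PAD{i}", f"padgene{i}"))
    return GeneDiseaseTable(records)


class TestSharedGenes:
    def test_identical_sets_score_100(self):
        gd = _gd({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert score_shared_genes(gd, "A", "B") == 100.0

    def test_disjoint_sets_score_0(self):
        gd = _gd({"A": {"g1"}, "B": {"g2"}})
        assert score_shared_genes(gd, "A", "B") == 0.0

    def test_partial_overlap_normalised_by_smaller_set(self):
        gd = _gd({"A": {"g1", "g2", "g3"}, "B": {"g2", "g3", "g4", "g5"}})
        assert score_shared_genes(gd, "A", "B") == pytest.approx(100 * 2 / 3)

    def test_unknown_disease_raises(self):
        gd = _gd({"A": {"g1"}, "B": {"g1"}})
        with pytest.raises(UnknownEntityError):
            score_shared_genes(gd, "A", "NOPE")


class TestUniqueness:
    @pytest.mark.parametrize(
        "d_g, d_total, expected",
        [(4, 4, 0.0), (1, 4, 0.5), (2, 50, 0.8)],
    )
    def test_gene_uniqueness_closed_form(self, d_g, d_total, expected):
        # gene 'shared' sits in d_g diseases out of d_total
        mapping = {f"D{i}": {"shared", f"u{i}"} for i in range(d_g)}
        gd = _gd(mapping, n_total=d_total)
        assert gene_uniqueness(gd, "shared") == pytest.approx(expected)

    def test_no_shared_genes_scores_zero(self):
        gd = _gd({"A": {"g1"}, "B": {"g2"}})
        assert score_uniqueness(gd, "A", "B") == 0.0

    def test_single_shared_gene(self):
        # one shared gene with D_g/D^T = 1/4 contributes 1 - sqrt(1/4) = 0.5;
        # a shared gene necessarily has D_g >= 2, so realise the ratio as 2/8
        gd = _gd({"A": {"s", "a"}, "B": {"s", "b"}}, n_total=8)
        assert score_uniqueness(gd, "A", "B") == pytest.approx(0.5)

    def test_shared_gene_sum_matches_per_gene_oracle(self, small_universe):
        gd = small_universe.gene_disease
        diseases = gd.diseases
        # independent oracle: sum 1 - sqrt(D_g / D^T) over the intersection
        for a, b in [(diseases[0], diseases[1]), (diseases[2], diseases[5])]:
            shared = gd.genes_of(a) & gd.genes_of(b)
            expected = sum(
                1 - math.sqrt(len(gd.diseases_of(g)) / gd.n_diseases) for g in shared
            )
            assert score_uniqueness(gd, a, b) == pytest.approx(expected)

    def test_frozen_two_gene_value(self):
        # shared genes with D_a = 1, D_b = 2 out of D^T = 50:
        # (1 - sqrt(0.02)) + (1 - sqrt(0.04)) = 1.65857864...
        vals = (1 - math.sqrt(1 / 50)) + (1 - math.sqrt(2 / 50))
        assert vals == pytest.approx(1.6585786437626906, abs=1e-12)
        # realised as a dataset: gene 'a' in A,B would have D_a = 2, so pin the
        # per-gene factors individually instead
        gd = _gd({"X": {"a"}, "A": {"b", "z1"}, "B": {"b", "z2"}}, n_total=50)
        assert gene_uniqueness(gd, "a") == pytest.approx(1 - math.sqrt(0.02))
        assert gene_uniqueness(gd, "b") == pytest.approx(1 - math.sqrt(0.04))

    def test_monotone_in_added_shared_gene(self):
        gd1 = _gd({"A": {"s", "a"}, "B": {"s", "b"}}, n_total=6)
        gd2 = _gd({"A": {"s", "t", "a"}, "B": {"s", "t", "b"}}, n_total=6)
        assert score_uniqueness(gd2, "A", "B") >= score_uniqueness(gd1, "A", "B")


def _ann(term_map):
    return GeneSetCollection([GeneSet(t, "BP", frozenset(gs)) for t, gs in term_map.items()])


class TestOntology:
    def test_identical_term_sets_score_100(self):
        gd = _gd({"A": {"g1"}, "B": {"g2"}})
        ann = _ann({"t1": {"g1", "g2"}, "t2": {"g1", "g2"}})
        assert score_ontology(gd, ann, "A", "B") == 100.0

    def test_disjoint_term_sets_score_0(self):
        gd = _gd({"A": {"g1"}, "B": {"g2"}})
        ann = _ann({"t1": {"g1"}, "t2": {"g2"}})
        assert score_ontology(gd, ann, "A", "B") == 0.0

    def test_jaccard_one_third(self):
        gd = _gd({"A": {"g1"}, "B": {"g2"}})
        ann = _ann({"t1": {"g1"}, "t2": {"g1", "g2"}, "t3": {"g2"}})
        assert score_ontology(gd, ann, "A", "B") == pytest.approx(100 / 3)

    def test_empty_union_is_an_error_not_zero(self):
        gd = _gd({"A": {"g1"}, "B": {"g2"}})
        ann = _ann({"t1": {"other"}})
        with pytest.raises(UndefinedScoreError):
            score_ontology(gd, ann, "A", "B")


class TestNetworkSeparation:
    def test_self_comparison_on_path(self, path_net):
        gd = _gd({"A": {"a", "b"}, "B": {"c"}})
        # D_ij = 0 (identical sets), D_ii = 1 -> s = -1
        assert score_network_separation(gd, path_net, "A", "A") == pytest.approx(-1.0)

    def test_printed_style_toy(self, path_net):
        gd = _gd({"A": {"a", "b"}, "B": {"c", "d"}})
        # D_ii = D_jj = 1; D_ij = (2+1+1+2)/4 = 1.5 -> s = 0.5
        assert score_network_separation(gd, path_net, "A", "B") == pytest.approx(0.5)
        assert separation_score("abcd", [("a", "b"), ("b", "c"), ("c", "d")],
                                ["a", "b"], ["c", "d"]) == pytest.approx(0.5)

    def test_isolated_disease_gene_gives_missing(self):
        net = Interactome.from_edges([("a", "b", None)], nodes=["z"])
        gd = _gd({"A": {"z"}, "B": {"a", "b"}})
        assert math.isnan(score_network_separation(gd, net, "A", "B"))

    def test_disease_absent_from_interactome_gives_missing(self, path_net):
        gd = _gd({"A": {"not_in_net"}, "B": {"a"}})
        assert math.isnan(score_network_separation(gd, path_net, "A", "B"))

    def test_shared_gene_contributes_zero_distance(self, path_net):
        gd = _gd({"A": {"a"}, "B": {"a", "d"}})
        # cross: a->0 (A side), a->0, d->3 (B side) => D_ij = 1; D_ii = 0, D_jj = 3
        assert score_network_separation(gd, path_net, "A", "B") == pytest.approx(1 - 1.5)

    def test_self_separation_nonpositive_on_random_connected_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(42)
        for trial in range(25):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            nodes = sorted(g.nodes)
            genes = [str(n) for n in rng.choice(nodes, size=min(4, len(nodes)), replace=False)]
            net = Interactome.from_edges([(str(a), str(b), None) for a, b in g.edges])
            gd = _gd({"A": set(genes), "B": {str(nodes[0])}})
            s = score_network_separation(gd, net, "A", "A")
            assert s <= 1e-12


class TestMatrix:
    def test_matrix_matches_pairwise_calls(self, small_universe):
        u = small_universe
        diseases = u.gene_disease.diseases[:5]
        for method in ("shared_genes", "uniqueness", "ontology", "network_separation"):
            m = comorbidity_matrix(
                u.gene_disease, method, diseases, ann=u.annotations, net=u.interactome
            )
            assert np.allclose(m.scores, m.scores.T, equal_nan=True)
            for i, a in enumerate(diseases):
                for j, b in enumerate(diseases):
                    if method == "shared_genes":
                        expect = score_shared_genes(u.gene_disease, a, b)
                    elif method == "uniqueness":
                        expect = score_uniqueness(u.gene_disease, a, b)
                    elif method == "ontology":
                        expect = score_ontology(u.gene_disease, u.annotations, a, b)
                    else:
                        expect = score_network_separation(u.gene_disease, u.interactome, a, b)
                    if math.isnan(expect):
                        assert math.isnan(m.scores[i, j])
                    else:
                        assert m.scores[i, j] == pytest.approx(expect)

    def test_identical_two_disease_fixture(self):
        gd = _gd({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        m = comorbidity_matrix(gd, "shared_genes", ["A", "B"])
        assert m.scores[0, 1] == 100.0
        assert m.risk_direction == "higher_is_risk"

    def test_disjoint_uniqueness_matrix_all_zero(self):
        gd = _gd({"A": {"a1"}, "B": {"b1"}, "C": {"c1"}})
        m = comorbidity_matrix(gd, "uniqueness", ["A", "B", "C"])
        off = m.scores[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)

    def test_missing_auxiliary_inputs_are_configuration_errors(self, tiny_gd):
        with pytest.raises(ConfigurationError):
            comorbidity_matrix(tiny_gd, "ontology", ["DA", "DB"])
        with pytest.raises(ConfigurationError):
            comorbidity_matrix(tiny_gd, "network_separation", ["DA", "DB"])
        with pytest.raises(ConfigurationError):
            comorbidity_matrix(tiny_gd, "shared_genes", ["DA"])

    def test_long_format_carries_shared_genes(self, tiny_gd):
        m = comorbidity_matrix(tiny_gd, "shared_genes", ["DA", "DB"])
        long = m.to_long_dataframe()
        assert long.loc[0, "shared_genes"] == "g2;g3"
        assert long.loc[0, "n_shared_genes"] == 2


@given(
    st.dictionaries(
        st.sampled_from(["A", "B", "C", "D"]),
        st.sets(st.sampled_from([f"g{i}" for i in range(10)]), min_size=1, max_size=6),
        min_size=2,
        max_size=4,
    )
)
def test_symmetry_and_ranges_hold_for_random_tables(mapping):
    gd = _gd(mapping)
    diseases = sorted(mapping)
    for a in diseases:
        for b in diseases:
            sg = score_shared_genes(gd, a, b)
            assert sg == score_shared_genes(gd, b, a)
            assert 0.0 <= sg <= 100.0
            su = score_uniqueness(gd, a, b)
            assert su == score_uniqueness(gd, b, a)
            assert su >= 0.0
    for a in diseases:
        assert score_shared_genes(gd, a, a) == 100.0
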