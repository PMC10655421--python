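import math
import random

import networkx as nx
import pytest

from conftest import brute_force_seed_compounds, random_network, rxn
from syncom.core import MetabolicNetwork
from syncom.reverse_ecology import (
    EmptySeedSetError,
    biosynthetic_support_score,
    build_compound_graph,
    competition_index,
    complementarity_index,
    compute_seed_set,
    metabolic_complementarity_index,
    pairwise_matrix,
    seed_set_of,
)


class TestCompoundGraph:
    def test_every_reactant_product_pair_is_an_edge(self, s1):
        g = build_compound_graph(s1)
        assert set(g.edges) == {("A", "C"), ("B", "C"), ("C", "D")}

    def test_reversible_adds_mirrored_edges(self):
        net = MetabolicNetwork(
            "x", (rxn("r1", {"X"}, {"Y"}, reversible=True), rxn("r2", {"Y"}, {"Z"}))
        )
        g = build_compound_graph(net)
        assert set(g.edges) == {("X", "Y"), ("Y", "X"), ("Y", "Z")}

    def test_exclusion_removes_nodes_and_incident_edges(self, s1):
        g = build_compound_graph(s1, exclude=["C"])
        assert set(g.nodes) == {"A", "B", "D"}
        assert g.number_of_edges() == 0

    def test_exclusion_never_adds_edges(self):
        rng = random.Random(5)
        for _ in range(20):
            net = random_network(rng, max_reactions=20)
            full = set(build_compound_graph(net).edges)
            some = rng.sample(sorted(net.compounds), 2)
            reduced = set(build_compound_graph(net, exclude=some).edges)
            assert reduced <= full


class TestSeedSet:
    def test_singleton_sources(self, s1):
        ss = seed_set_of(s1)
        assert ss.entries == {"A": 1.0, "B": 1.0}
        assert ss.components == (("A",), ("B",))

    def test_cycle_shares_confidence(self):
        net = MetabolicNetwork(
            "x", (rxn("r1", {"X"}, {"Y"}, reversible=True), rxn("r2", {"Y"}, {"Z"}))
        )
        ss = seed_set_of(net)
        assert ss.entries == {"X": 0.5, "Y": 0.5}
        assert "Z" not in ss.entries

    def test_isolated_node_is_its_own_seed(self):
        g = nx.DiGraph()
        g.add_node("lone")
        assert compute_seed_set(g, owner="x").entries == {"lone": 1.0}

    def test_empty_graph_empty_seed_set(self):
        assert compute_seed_set(nx.DiGraph(), owner="x").entries == {}

    def test_confidences_sum_to_one_per_component(self):
        rng = random.Random(17)
        for _ in range(50):
            net = random_network(rng, max_reactions=30)
            ss = seed_set_of(net)
            for comp in ss.components:
                assert math.isclose(sum(ss.entries[c] for c in comp), 1.0)

    def test_matches_reachability_characterization_on_random_graphs(self):
        rng = random.Random(31)
        for i in range(120):
            net = random_network(rng, max_reactions=30)
            g = build_compound_graph(net)
            got = set(seed_set_of(net).entries)
            assert got == brute_force_seed_compounds(g), f"case {i}"


class TestIndices:
    def test_identical_seed_sets_compete_fully(self, s1):
        ss = seed_set_of(s1)
        assert competition_index(ss, ss) == 1.0

    def test_partial_overlap(self):
        a = MetabolicNetwork("a", (rxn("r1", {"A"}, {"P"}), rxn("r2", {"B"}, {"P"})))
        b = MetabolicNetwork("b", (rxn("r1", {"B"}, {"Q"}), rxn("r2", {"C"}, {"Q"})))
        assert competition_index(seed_set_of(a), seed_set_of(b)) == 0.5

    def test_disjoint_seed_sets_no_competition(self, s1):
        other = MetabolicNetwork("o", (rxn("r", {"X"}, {"Y"}),))
        assert competition_index(seed_set_of(s1), seed_set_of(other)) == 0.0

    def test_empty_focal_seed_set_is_an_error(self, s1):
        cycle = MetabolicNetwork(
            "c", (rxn("r", {"X"}, {"Y"}, reversible=True),)
        )
        # a pure 2-cycle still has one source SCC; build a truly empty one
        import networkx as nx_
        empty = compute_seed_set(nx_.DiGraph(), owner="void")
        with pytest.raises(EmptySeedSetError):
            competition_index(empty, seed_set_of(s1))
        assert cycle is not None  # silence lint

    def test_complementarity_counts_partner_nonseed_compounds(self):
        focal = MetabolicNetwork("f", (rxn("r1", {"A"}, {"P"}), rxn("r2", {"B"}, {"P"})))
        partner = MetabolicNetwork("p", (rxn("r1", {"Q"}, {"A"}),))
        # partner compounds {Q, A}; partner seeds {Q}; focal seeds {A, B}
        assert complementarity_index(seed_set_of(focal), partner) == 0.5

    def test_self_complementarity_zero(self, s1):
        assert complementarity_index(seed_set_of(s1), s1) == 0.0

    def test_bss_counts_any_supporter_compound(self):
        consumer = MetabolicNetwork(
            "c", (rxn("r1", {"A"}, {"P"}), rxn("r2", {"B"}, {"P"}))
        )
        supporter = MetabolicNetwork("s", (rxn("r", {"A"}, {"Q"}),))
        assert biosynthetic_support_score(seed_set_of(consumer), supporter) == 0.5

    def test_bss_self_support_total(self, s1):
        assert biosynthetic_support_score(seed_set_of(s1), s1) == 1.0

    def test_mci_equals_complementarity(self, s1, s2):
        ss = seed_set_of(s1)
        assert metabolic_complementarity_index(ss, s2) == complementarity_index(ss, s2)

    def test_weighted_vs_unweighted_differ_on_cycles(self):
        # focal: source 2-cycle {X,Y} plus singleton source {W}
        focal = MetabolicNetwork(
            "f",
            (rxn("r1", {"X"}, {"Y"}, reversible=True),
             rxn("r2", {"Y"}, {"Z"}),
             rxn("r3", {"W"}, {"Z"})),
        )
        partner = MetabolicNetwork("p", (rxn("r", {"X"}, {"o"}),))
        fs, ps = seed_set_of(focal), seed_set_of(partner)
        weighted = competition_index(fs, ps, weighted=True)
        unweighted = competition_index(fs, ps, weighted=False)
        assert math.isclose(weighted, 0.25)   # 0.5 / (0.5+0.5+1)
        assert math.isclose(unweighted, 1 / 3)

    def test_indices_stay_in_unit_interval_on_random_pairs(self):
        rng = random.Random(77)
        for _ in range(30):
            a = random_network(rng, species_id="a", max_reactions=20)
            b = random_network(rng, species_id="b", max_reactions=20)
            sa, sb = seed_set_of(a), seed_set_of(b)
            if not sa.entries or not sb.entries:
                continue
            for val in (
                competition_index(sa, sb),
                complementarity_index(sa, b, sb),
                biosynthetic_support_score(sa, b),
            ):
                assert 0.0 <= val <= 1.0


class TestPairwiseMatrix:
    def test_identical_networks_full_competition(self, s1):
        twin = MetabolicNetwork("S1twin", s1.reactions)
        mat = pairwise_matrix([s1, twin], "competition")
        assert mat.loc["S1", "S1twin"] == 1.0
        assert mat.loc["S1twin", "S1"] == 1.0

    def test_complementarity_diagonal_zero(self, s1, s2):
        mat = pairwise_matrix([s1, s2], "complementarity")
        assert (mat.values.diagonal() == 0.0).all()

    def test_competition_diagonal_one(self, s1, s2):
        mat = pairwise_matrix([s1, s2], "competition")
        assert (mat.values.diagonal() == 1.0).all()

    def test_three_species_matrix_matches_per_pair_calls(self):
        rng = random.Random(3)
        nets = [random_network(rng, species_id=f"sp{j}", max_reactions=12)
                for j in range(3)]
        seeds = {n.species_id: seed_set_of(n) for n in nets}
        mat = pairwise_matrix(nets, "competition")
        for f in nets:
            for p in nets:
                expected = competition_index(seeds[f.species_id],
                                             seeds[p.species_id])
                assert mat.loc[f.species_id, p.species_id] == expected

    def test_unknown_metric_rejected(self, s1, s2):
        with pytest.raises(ValueError):
            pairwise_matrix([s1, s2], "synergy")
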