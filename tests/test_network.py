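"""DAG handling, structure-learner stand-in, neighborhoods, KDA, locus ranking."""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungeqtl import network as net


def hypergeom_upper_oracle(x: int, k: int, m: int, n: int) -> Fraction:
    """Exact upper tail by full enumeration with rational arithmetic."""
    total = math.comb(m + n, k)
    acc = Fraction(0)
    for j in range(x, min(k, m) + 1):
        acc += Fraction(math.comb(m, j) * math.comb(n, k - j), total)
    return acc


class TestLoadNetwork:
    def test_valid_edge_list(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("parent_gene\tchild_gene\na\tb\nb\tc\n")
        g = net.load_network(f)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g.has_edge("A", "B")  # symbols uppercased

    def test_cycle_raises_with_offending_path(self):
        with pytest.raises(ValueError, match="cycle"):
            net.load_network([("a", "b"), ("b", "a")])

    def test_duplicate_edge_warns_and_dedupes(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = net.load_network([("a", "b"), ("a", "b"), ("b", "c")])
        assert g.number_of_edges() == 2

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="elf-loop"):
            net.load_network([("a", "a")])


class TestStructureLearner:
    def _chain_data(self, rng, n=400):
        a = rng.normal(size=n)
        b = 0.9 * a + 0.45 * rng.normal(size=n)
        c = 0.9 * b + 0.45 * rng.normal(size=n)
        return pd.DataFrame([a, b, c], index=["A", "B", "C"])

    def test_chain_skeleton_recovery(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = net.learn_network_standin(self._chain_data(rng))
            skeleton = {frozenset(e) for e in g.edges()}
            hits += skeleton == {frozenset({"A", "B"}), frozenset({"B", "C"})}
        assert hits >= 18  # >= 90% of seeds

    def test_independent_noise_is_near_edgeless(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(20, 500)), index=[f"N{i}" for i in range(20)]
        )
        g = net.learn_network_standin(expr)
        assert g.number_of_edges() <= 2

    def test_output_is_always_valid(self):
        rng = np.random.default_rng(1)
        g = net.learn_network_standin(self._chain_data(rng))
        net.validate_network(g)  # raises on failure

    def test_too_few_samples_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            net.learn_network_standin(self._chain_data(rng, n=30))

    def test_deterministic_given_data(self):
        rng = np.random.default_rng(3)
        data = self._chain_data(rng)
        g1 = net.learn_network_standin(data)
        g2 = net.learn_network_standin(data)
        assert set(g1.edges()) == set(g2.edges())


class TestNeighborhood:
    def _chain(self):
        return net.load_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])

    def test_three_edges_from_chain_head(self):
        assert net.neighborhood(self._chain(), "A", 3) == {"B", "C", "D"}

    def test_h_zero_is_empty(self):
        assert net.neighborhood(self._chain(), "A", 0) == set()

    def test_isolated_node_has_empty_neighborhood(self):
        g = self._chain()
        g.add_node("Z")
        assert net.neighborhood(g, "Z", 3) == set()

    def test_direction_ignored(self):
        g = net.load_network([("b", "a"), ("b", "c")])
        assert net.neighborhood(g, "A", 2) == {"B", "C"}

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            net.neighborhood(self._chain(), "NOPE")

    @given(st.integers(min_value=0, max_value=5))
    def test_neighborhood_monotone_in_h(self, h):
        g = self._chain()
        assert net.neighborhood(g, "B", h) <= net.neighborhood(g, "B", h + 1)

    def test_downstream_respects_direction(self):
        g = self._chain()
        assert net.downstream(g, "C", 3) == {"D", "E"}
        assert net.downstream(g, "E", 3) == set()


class TestExtractSubnetwork:
    def test_highest_seed_proportion_wins(self):
        # component 1: 10 nodes, 6 seeds; component 2: 30 nodes, 3 seeds
        edges = [(f"a{i}", f"a{i+1}") for i in range(9)]
        edges += [(f"b{i}", f"b{i+1}") for i in range(29)]
        g = net.load_network(edges)
        seeds = [f"A{i}" for i in range(6)] + ["B0", "B1", "B2"]
        sub, rep = net.extract_subnetwork(g, seeds, h=30)
        assert rep["n_nodes"] == 10
        assert rep["seed_proportion"] == pytest.approx(0.6)

    def test_tie_broken_toward_larger_component(self):
        edges = [(f"a{i}", f"a{i+1}") for i in range(7)]  # 8 nodes
        edges += [(f"b{i}", f"b{i+1}") for i in range(19)]  # 20 nodes
        g = net.load_network(edges)
        seeds = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(10)]
        sub, rep = net.extract_subnetwork(g, seeds, h=30)
        assert rep["n_nodes"] == 20

    def test_single_component_returns_itself(self):
        g = net.load_network([("a", "b"), ("b", "c")])
        sub, rep = net.extract_subnetwork(g, ["A"], h=3)
        assert set(sub.nodes()) == {"A", "B", "C"}

    def test_subnetwork_is_weakly_connected(self, small_dataset):
        g = small_dataset.network
        seeds = list(g.nodes())[:5]
        sub, _ = net.extract_subnetwork(g, seeds, h=3)
        assert nx.is_weakly_connected(sub)

    def test_no_seed_present_raises(self):
        g = net.load_network([("a", "b")])
        with pytest.raises(ValueError):
            net.extract_subnetwork(g, ["zzz"])


class TestHypergeomUpper:
    def test_small_population_enumeration(self):
        # all draws of 2 from {2 successes, 2 failures}: P(X>=2) = 1/6
        assert net.hypergeom_upper(2, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    @given(
        st.integers(min_value=0, max_value=12),
        st.integers(min_value=0, max_value=13),
    )
    def test_matches_enumeration_up_to_25(self, m, n):
        if m + n == 0:
            return
        for k in range(0, m + n + 1, max(1, (m + n) // 4)):
            for x in range(0, min(k, m) + 1):
                exact = float(hypergeom_upper_oracle(x, k, m, n))
                assert net.hypergeom_upper(x, k, m, n) == pytest.approx(
                    exact, abs=1e-12
                )

    def test_x_zero_returns_one_exactly(self):
        assert net.hypergeom_upper(0, 0, 119, 7000) == 1.0
        assert net.hypergeom_upper(0, 50, 119, 7000) == 1.0

    def test_monotone_nonincreasing_in_x(self):
        vals = [net.hypergeom_upper(x, 130, 119, 7000) for x in range(0, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            net.hypergeom_upper(5, 4, 119, 7000)
        with pytest.raises(ValueError):
            net.hypergeom_upper(1, 8000, 119, 7000)


class TestKeyDriverAnalysis:
    def _hub_graph(self):
        g = nx.DiGraph()
        g.add_edges_from(("HUB", f"L{i}") for i in range(10))
        g.add_nodes_from(f"X{i}" for i in range(9))  # 20 nodes total
        return g

    def test_planted_hub_worked_example(self):
        # x=8 of k=10 downstream genes in an 8-gene target set over 20 nodes:
        # P = C(8,8) C(12,2) / C(20,10) = 66/184756
        report = net.key_driver_analysis(self._hub_graph(), [f"L{i}" for i in range(8)])
        top = report.iloc[0]
        assert top["gene"] == "HUB"
        assert top["p"] == pytest.approx(66 / 184756, rel=1e-10)
        assert top["driver"]  # survives Bonferroni across 20 genes

    def test_leaf_nodes_never_drive(self):
        report = net.key_driver_analysis(self._hub_graph(), [f"L{i}" for i in range(8)])
        leaves = report[report["gene"].str.startswith("L")]
        assert (leaves["k_draw"] == 0).all()
        assert (leaves["p"] == 1.0).all()
        assert not leaves["driver"].any()

    def test_disjoint_targets_yield_no_drivers(self):
        report = net.key_driver_analysis(self._hub_graph(), [f"X{i}" for i in range(5)])
        assert not report["driver"].any()

    def test_empty_target_intersection_raises(self):
        with pytest.raises(ValueError):
            net.key_driver_analysis(self._hub_graph(), ["NOT_THERE"])


class TestRankLocusCandidates:
    def _graph(self):
        edges = [("c1", f"m{i}") for i in range(6)]
        edges += [("c2", f"z{i}") for i in range(6)]
        edges += [(f"pad{i}", f"pad{i+1}") for i in range(30)]
        return net.load_network(edges)

    def test_candidate_absent_from_network_scores_one(self):
        table = net.rank_locus_candidates(self._graph(), ["c1", "ghost"], ["M0", "M1"])
        ghost = table[table["gene"] == "GHOST"].iloc[0]
        assert (ghost["x"], ghost["k_draw"], ghost["p"]) == (0, 0, 1.0)

    def test_canonical_rich_candidate_ranks_first(self):
        canon = [f"M{i}" for i in range(6)]
        table = net.rank_locus_candidates(self._graph(), ["c1", "c2"], canon)
        assert table.iloc[0]["gene"] == "C1"
        assert table.iloc[0]["x"] == 6
        assert table.iloc[0]["p"] < table.iloc[1]["p"]

    def test_identical_neighborhoods_score_identically(self):
        g = net.load_network([("a", "m0"), ("b", "m0")])
        table = net.rank_locus_candidates(g, ["a", "b"], ["M0"], h=1)
        assert table["p"].nunique() == 1

    def test_explicit_background_size(self):
        canon = [f"M{i}" for i in range(6)]
        small = net.rank_locus_candidates(self._graph(), ["c1"], canon)
        big = net.rank_locus_candidates(self._graph(), ["c1"], canon, background=16606)
        # a larger background makes the same overlap more surprising
        assert big.iloc[0]["p"] < small.iloc[0]["p"]

    def test_empty_canonical_raises(self):
        with pytest.raises(ValueError):
            net.rank_locus_candidates(self._graph(), ["c1"], [])
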