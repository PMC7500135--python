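import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netsketch import propagation as prop
from netsketch import synthetic_data as sd
from netsketch.propagation import ShellDecomposition

from conftest import bfs_distances_scipy


class TestHubDegrees:
    def test_star_center(self):
        g = nx.star_graph(4)  # center 0
        assert prop.hub_degrees(g, [0]) == [(0, 4)]

    def test_fixture_hub_table(self, bat_network):
        ranked = prop.hub_degrees(bat_network, list(sd.BAT_HUB_DEGREES))
        assert ranked == list(sd.BAT_HUB_DEGREES.items())
        assert ranked[0] == ("BatD", 55)

    def test_fixture_hubs_are_global_top(self, bat_network):
        all_ranked = prop.hub_degrees(bat_network, list(bat_network.nodes))
        assert [n for n, _ in all_ranked[:8]] == list(sd.BAT_HUB_DEGREES)

    def test_missing_seed_degree_zero(self):
        assert prop.hub_degrees(nx.path_graph(3), ["nope"]) == [("nope", 0)]

    def test_er_matches_adjacency_recount(self):
        g = nx.gnp_random_graph(80, 0.08, seed=2)
        seeds = [3, 1, 4, 15, 9]
        ranked = dict(prop.hub_degrees(g, seeds))
        for s in seeds:
            assert ranked[s] == len(list(g.adj[s]))

    def test_tie_break_lexicographic(self):
        g = nx.path_graph(["b", "a", "c", "d"])
        ranked = prop.hub_degrees(g, ["c", "a"])  # both degree 2
        assert ranked == [("a", 2), ("c", 2)]


class TestDegreeStats:
    def test_star_k13_hand_values(self):
        s = prop.degree_stats(nx.star_graph(3))
        assert s.mean_degree == 1.5
        assert s.second_moment == 3.0
        assert s.alpha_paper == 2.0
        assert s.branching == 1.0
        assert s.prefactor == 2.0

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_regular_branching_exact(self, k):
        g = nx.random_regular_graph(k, 20, seed=1)
        assert prop.degree_stats(g).branching == pytest.approx(k - 1, abs=1e-12)

    def test_er_matches_direct_summation(self):
        g = nx.gnp_random_graph(500, 0.02, seed=9)
        s = prop.degree_stats(g)
        degs = [len(list(g.adj[n])) for n in g.nodes]  # independent recount
        assert s.mean_degree == pytest.approx(sum(degs) / len(degs))
        assert s.second_moment == pytest.approx(sum(d * d for d in degs) / len(degs))
        assert s.alpha_paper == pytest.approx(s.second_moment / s.mean_degree)

    def test_includes_degree_zero_nodes(self):
        g = nx.path_graph(2)
        g.add_node("isolated")
        assert prop.degree_stats(g).mean_degree == pytest.approx(2 / 3)

    def test_edgeless_errors(self):
        g = nx.empty_graph(5)
        with pytest.raises(ValueError, match="degenerate"):
            prop.degree_stats(g)

    def test_jensen_inequality_random(self):
        for seed in range(20):
            g = nx.gnp_random_graph(40, 0.1, seed=seed)
            if g.number_of_edges() == 0:
                continue
            s = prop.degree_stats(g)
            assert s.second_moment >= s.mean_degree**2 - 1e-12
            assert s.alpha_paper >= s.mean_degree - 1e-12
            assert s.branching >= 0


class TestShellDecomposition:
    def test_path(self):
        d = prop.shell_decomposition(nx.path_graph(["A", "B", "C"]), "A")
        assert d.shells == (frozenset("A"), frozenset("B"), frozenset("C"))

    def test_binary_tree_powers_of_two(self):
        g = nx.balanced_tree(2, 5)
        d = prop.shell_decomposition(g, 0, r_max=5)
        assert d.sizes == tuple(2**r for r in range(6))

    def test_r_max_truncates(self):
        g = nx.path_graph(10)
        d = prop.shell_decomposition(g, 0, r_max=3)
        assert len(d.shells) == 4
        assert d.n_reachable == 4

    def test_missing_seed_errors(self):
        with pytest.raises(KeyError):
            prop.shell_decomposition(nx.path_graph(3), "zz")

    def test_er_shells_match_scipy_distances(self):
        g = nx.gnp_random_graph(200, 0.03, seed=4)
        d = prop.shell_decomposition(g, 0, r_max=200)
        oracle = bfs_distances_scipy(g, 0)
        for r, shell in enumerate(d.shells):
            for node in shell:
                assert oracle[node] == r
        assert d.n_reachable == len(oracle)

    def test_shells_partition_reachable(self):
        for seed in range(10):
            g = nx.gnp_random_graph(60, 0.05, seed=seed)
            d = prop.shell_decomposition(g, 0, r_max=60)
            union = set().union(*d.shells)
            assert sum(d.sizes) == len(union)  # pairwise disjoint
            assert union == set(nx.node_connected_component(g, 0))

    def test_each_shell_links_to_previous(self):
        g = nx.gnp_random_graph(80, 0.06, seed=6)
        d = prop.shell_decomposition(g, 0, r_max=80)
        for r in range(1, len(d.shells)):
            for node in d.shells[r]:
                assert any(nb in d.shells[r - 1] for nb in g.adj[node])


def decomp_from_sizes(sizes):
    """Synthetic decomposition with the requested shell sizes."""
    shells, start = [], 0
    for s in sizes:
        shells.append(frozenset(range(start, start + s)))
        start += s
    return ShellDecomposition("seed", tuple(shells))


class TestPropagationProfile:
    def test_hand_normalization(self):
        p = prop.propagation_profile(decomp_from_sizes([1, 2, 4, 8, 4, 1]))
        assert p.d_of_r == (0.05, 0.10, 0.20, 0.40, 0.20, 0.05)
        assert p.r_s == 3
        assert p.growth_rate == pytest.approx(math.log(2))

    def test_uniform_path_first_max(self):
        p = prop.propagation_profile(decomp_from_sizes([1, 1, 1]))
        assert p.d_of_r == (1 / 3, 1 / 3, 1 / 3)
        assert p.r_s == 0
        assert math.isnan(p.growth_rate)

    def test_bary_tree_growth_rate(self):
        g = nx.balanced_tree(3, 6)
        p = prop.propagation_profile(prop.shell_decomposition(g, 0, r_max=6))
        assert abs(p.growth_rate - math.log(3)) < 0.05

    def test_isolated_seed_degenerate(self):
        g = nx.empty_graph(1)
        p = prop.propagation_profile(prop.shell_decomposition(g, 0))
        assert p.d_of_r == (1.0,)
        assert p.r_s == 0 and p.degenerate and math.isnan(p.growth_rate)

    def test_sums_to_one_on_random_graphs(self):
        for seed in range(10):
            g = nx.gnp_random_graph(50, 0.08, seed=seed)
            p = prop.propagation_profile(prop.shell_decomposition(g, 0))
            assert sum(p.d_of_r) == pytest.approx(1.0)


class TestSaturationRadius:
    def test_hand_example(self):
        assert prop.saturation_radius([0.05, 0.10, 0.20, 0.40, 0.20, 0.05]) == 3

    def test_constant_sequence(self):
        assert prop.saturation_radius([0.2] * 5 ) == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            prop.saturation_radius([])

    def test_random_unimodal_matches_scan(self, rng):
        for _ in range(100):
            peak = int(rng.integers(0, 10))
            rise = np.sort(rng.uniform(0, 1, size=peak))
            fall = -np.sort(-rng.uniform(0, rise[-1] if peak else 1, size=int(rng.integers(0, 6))))
            seq = list(rise) + list(fall)
            if not seq:
                continue
            # linear-scan first-argmax oracle
            best, best_i = -1.0, 0
            for i, v in enumerate(seq):
                if v > best:
                    best, best_i = v, i
            assert prop.saturation_radius(seq) == best_i

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20), st.data())
    def test_moving_max_earlier_never_increases(self, seq, data):
        r0 = prop.saturation_radius(seq)
        j = data.draw(st.integers(0, r0)) if r0 > 0 else 0
        moved = list(seq)
        moved.insert(j, max(seq))
        assert prop.saturation_radius(moved) <= r0 + 1
        assert prop.saturation_radius(moved) == j if max(seq) > 0 else True


class TestModelProfile:
    def test_unit_branching(self):
        stats = prop.DegreeStats(1, 1, 1, branching=1.0, prefactor=2.0)
        assert prop.model_profile(stats, [0, 1, 2]) == [2, 2, 2]

    def test_regular_tree_ratio(self):
        b = 4
        stats = prop.DegreeStats(0, 0, 0, branching=b - 1, prefactor=1.5)
        vals = prop.model_profile(stats, [0, 1, 2, 3])
        ratios = [vals[i + 1] / vals[i] for i in range(3)]
        assert ratios == pytest.approx([b - 1] * 3)

    def test_er_empirical_ratio_near_branching(self):
        g = nx.gnp_random_graph(2000, 0.005, seed=8)
        stats = prop.degree_stats(g)
        d = prop.shell_decomposition(g, 0, r_max=3)
        ratio = d.sizes[2] / d.sizes[1]
        assert abs(ratio - stats.branching) / stats.branching < 0.25

    def test_no_expansion_errors(self):
        stats = prop.DegreeStats(1, 1, 1, branching=0.0, prefactor=math.inf)
        with pytest.raises(ValueError):
            prop.model_profile(stats, [0, 1])


class TestAnalyzeSeeds:
    def test_fixture_profiles_normalized(self, bat_network):
        profiles = prop.analyze_seeds(bat_network, list(sd.BAT_HUB_DEGREES))
        assert len(profiles) == 8
        for p in profiles:
            assert sum(p.d_of_r) == pytest.approx(1.0)

    def test_duplicate_seed_duplicate_rows(self, bat_network):
        profiles = prop.analyze_seeds(bat_network, ["BatD", "BatD"])
        assert profiles[0] == profiles[1]

    def test_matches_single_seed_calls(self):
        g = nx.gnp_random_graph(100, 0.05, seed=10)
        seeds = list(range(8))
        batch = prop.analyze_seeds(g, seeds)
        for s, p in zip(seeds, batch):
            single = prop.propagation_profile(prop.shell_decomposition(g, s))
            assert p == single

    def test_missing_seed_flagged_not_fatal(self, bat_network):
        profiles = prop.analyze_seeds(bat_network, ["BatD", "ghost"])
        assert not profiles[0].degenerate
        assert profiles[1].degenerate and profiles[1].d_of_r == (1.0,)

    def test_summary_columns(self, bat_network):
        profiles = prop.analyze_seeds(bat_network, list(sd.BAT_HUB_DEGREES))
        table = prop.summarize(bat_network, profiles)
        assert list(table["degree"]) == list(sd.BAT_HUB_DEGREES.values())
        assert set(table.columns) >= {"seed", "degree", "r_s", "growth_rate", "peak_d"}
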