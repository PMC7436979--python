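import itertools

import numpy as np
import pytest

from netpharm.model import InteractionNetwork, PPIEdge
from netpharm.topology import (
    centralities,
    degree_betweenness_profile,
    screen_key_targets,
)
from tests.conftest import make_network


# ---------------------------------------------------------------------------
# independent oracle: exhaustive shortest-path enumeration
# ---------------------------------------------------------------------------

def brute_force_centralities(nodes, edges):
    """All-pairs shortest-path enumeration by brute force.

    Enumerates every simple path between every node pair (feasible for
    tiny graphs), keeps the minimum-length ones, and derives betweenness
    (normalized by (N-1)(N-2)/2) and closeness (reciprocal mean distance
    to reachable nodes) directly from the path lists.
    """
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_simple_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    dist = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths) - 1
        shortest = [p for p in paths if len(p) - 1 == d]
        dist[(s, t)] = d
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / len(shortest)
    pair_count = (n - 1) * (n - 2) / 2
    betweenness = {v: bc[v] / pair_count if pair_count else 0.0 for v in nodes}
    closeness = {}
    for v in nodes:
        ds = [d for (s, t), d in dist.items() if v in (s, t)]
        closeness[v] = len(ds) / sum(ds) if ds else 0.0
    return betweenness, closeness


class TestCentralities:
    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            centralities(InteractionNetwork())

    def test_path5(self, path5):
        table = centralities(path5)
        assert table.loc["C", "betweenness"] == pytest.approx(4 / 6, abs=1e-12)
        assert table.loc["A", "closeness"] == pytest.approx(0.4, abs=1e-12)
        assert table.loc["A", "degree"] == 1
        assert table.loc["C", "degree"] == 2

    def test_star5(self, star5):
        table = centralities(star5)
        assert table.loc["HUB", "degree"] == 4
        assert table.loc["HUB", "betweenness"] == pytest.approx(1.0)
        assert table.loc["HUB", "closeness"] == pytest.approx(1.0)
        for leaf in ("L1", "L2", "L3", "L4"):
            assert table.loc[leaf, "betweenness"] == 0.0
            assert table.loc[leaf, "closeness"] == pytest.approx(1 / 1.75)

    def test_complete_k4(self):
        net = make_network(
            [(a, b, 1.0) for a, b in itertools.combinations("ABCD", 2)]
        )
        table = centralities(net)
        assert (table["betweenness"] == 0.0).all()
        assert (table["closeness"] == 1.0).all()

    def test_isolated_node_closeness_zero(self):
        net = InteractionNetwork()
        net.add_node("A", "neighbor")
        table = centralities(net)
        assert table.loc["A", "closeness"] == 0.0
        assert table.loc["A", "degree"] == 0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            names = [f"N{i}" for i in range(n)]
            edges = [
                (a, b)
                for a, b in itertools.combinations(names, 2)
                if rng.random() < 0.45
            ]
            net = InteractionNetwork()
            for name in names:
                net.add_node(name, "neighbor")
            for a, b in edges:
                net.add_edge(PPIEdge(a, b, 1.0))
            table = centralities(net)
            bc, cc = brute_force_centralities(names, edges)
            for v in names:
                assert table.loc[v, "betweenness"] == pytest.approx(bc[v], abs=1e-9)
                assert table.loc[v, "closeness"] == pytest.approx(cc[v], abs=1e-9)

    def test_disconnected_components_match_separate_runs(self):
        whole = make_network(
            [("A", "B", 1.0), ("B", "C", 1.0), ("X", "Y", 1.0)]
        )
        part1 = make_network([("A", "B", 1.0), ("B", "C", 1.0)])
        part2 = make_network([("X", "Y", 1.0)])
        t = centralities(whole)
        t1 = centralities(part1)
        t2 = centralities(part2)
        for v in ("A", "B", "C"):
            assert t.loc[v, "closeness"] == pytest.approx(t1.loc[v, "closeness"])
        for v in ("X", "Y"):
            assert t.loc[v, "closeness"] == pytest.approx(t2.loc[v, "closeness"])

    def test_betweenness_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            names = [f"N{i}" for i in range(n)]
            edges = [
                (a, b, 1.0)
                for a, b in itertools.combinations(names, 2)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            table = centralities(make_network(edges))
            assert ((table["betweenness"] >= 0) & (table["betweenness"] <= 1)).all()
            assert ((table["closeness"] >= 0) & (table["closeness"] <= 1)).all()


class TestScreenKeyTargets:
    def test_star5(self, star5):
        result = screen_key_targets(centralities(star5))
        assert result.degree_cutoff == pytest.approx(2.0)
        assert result.betweenness_cutoff == pytest.approx(0.0)
        assert result.closeness_cutoff == pytest.approx(1 / 1.75)
        assert result.key_targets == {"HUB"}

    def test_path5_empty(self, path5):
        result = screen_key_targets(centralities(path5))
        assert result.degree_cutoff == pytest.approx(4.0)
        assert result.key_targets == set()

    def test_strict_inequality_at_cutoff(self):
        # every node of K4 sits exactly at the medians: strict > keeps none
        net = make_network(
            [(a, b, 1.0) for a, b in itertools.combinations("ABCD", 2)]
        )
        result = screen_key_targets(centralities(net))
        assert result.key_targets == set()

    def test_relabeling_invariance(self, star5):
        table = centralities(star5)
        mapping = {"HUB": "ZZZ", "L1": "A1", "L2": "A2", "L3": "A3", "L4": "A4"}
        relabeled = table.rename(index=mapping)
        r1 = screen_key_targets(table)
        r2 = screen_key_targets(relabeled)
        assert {mapping[g] for g in r1.key_targets} == r2.key_targets

    def test_empty_table_errors(self, star5):
        table = centralities(star5)
        with pytest.raises(ValueError):
            screen_key_targets(table.iloc[0:0])


class TestDegreeBetweennessProfile:
    def test_single_node(self):
        net = InteractionNetwork()
        net.add_node("A", "neighbor")
        profile = degree_betweenness_profile(centralities(net))
        assert len(profile) == 1
        assert profile.loc[0, "gene"] == "A"

    def test_star_order_and_tiebreak(self, star5):
        profile = degree_betweenness_profile(centralities(star5))
        assert profile["gene"].tolist() == ["HUB", "L1", "L2", "L3", "L4"]

    def test_planted_hubs_rank_high_on_both(self):
        from scipy.stats import spearmanr

        from netpharm.network import build_ct_ot_network, common_targets, extract_hub_network
        from netpharm.synthetic import SyntheticConfig, generate_dataset

        ds = generate_dataset(SyntheticConfig(seed=3))
        net = build_ct_ot_network(
            ds.compound_targets, ds.disease_targets, ds.ppi_edges
        )
        common = common_targets(ds.compound_targets, ds.disease_targets)
        hub = extract_hub_network(net, common & net.nodes)
        profile = degree_betweenness_profile(centralities(hub))
        rho, _ = spearmanr(profile["degree"], profile["betweenness"])
        assert rho > 0
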