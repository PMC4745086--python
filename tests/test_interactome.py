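"""Network inference, topology metrics, power-law fit and Steiner trees."""

import itertools
from collections import Counter, deque

import networkx as nx
import numpy as np
import pytest

import snailnet as sn
from snailnet.errors import ValidationError
from snailnet.formats import DomainInteraction


def _asg(pid, domains):
    return sn.DomainAssignment(pid, frozenset(domains))


def _ddi(a, b, conf="HC"):
    x, y = sorted((a, b))
    return DomainInteraction(x, y, conf)


class TestBuildNetwork:
    def test_basic_edge(self):
        net = sn.build_network([_asg("p", {"PF1"}), _asg("q", {"PF2"})],
                               [_ddi("PF1", "PF2")])
        assert net.edges == [("p", "q")]
        assert net.evidence("p", "q") == {("PF1", "PF2")}

    def test_self_interacting_domain_links_distinct_proteins_only(self):
        net = sn.build_network([_asg("p", {"PF1"}), _asg("q", {"PF1"})],
                               [_ddi("PF1", "PF1")])
        assert net.edges == [("p", "q")]
        assert not any(u == v for u, v in net.graph.edges)

    def test_isolated_proteins_excluded(self):
        net = sn.build_network(
            [_asg("p", {"PF1"}), _asg("q", {"PF2"}), _asg("r", {"PF9"})],
            [_ddi("PF1", "PF2")],
        )
        assert net.nodes == ["p", "q"]

    def test_matches_all_pairs_oracle(self):
        """30 random proteins x 10 domains vs an O(n^2) oracle."""
        rng = np.random.default_rng(0)
        domains = [f"PF{i}" for i in range(10)]
        asg = [
            _asg(f"p{i:02d}",
                 rng.choice(domains, size=rng.integers(1, 4), replace=False))
            for i in range(30)
        ]
        pairs = [
            (a, b)
            for a, b in itertools.combinations_with_replacement(domains, 2)
            if rng.random() < 0.3
        ]
        ddis = [_ddi(a, b) for a, b in pairs]
        net = sn.build_network(asg, ddis)
        ddi_set = {tuple(sorted(p)) for p in pairs}
        oracle = set()
        for x, y in itertools.combinations(asg, 2):
            if any(
                tuple(sorted((da, db))) in ddi_set
                for da in x.domains
                for db in y.domains
            ):
                oracle.add(tuple(sorted((x.protein_id, y.protein_id))))
        assert set(net.edges) == oracle

    def test_edge_set_monotone_in_ddis(self):
        rng = np.random.default_rng(1)
        domains = [f"PF{i}" for i in range(8)]
        asg = [
            _asg(f"p{i}",
                 rng.choice(domains, size=rng.integers(1, 3), replace=False))
            for i in range(20)
        ]
        all_pairs = list(itertools.combinations_with_replacement(domains, 2))
        rng.shuffle(all_pairs)
        prev = set()
        for k in (3, 8, 15, len(all_pairs)):
            net = sn.build_network(asg, [_ddi(a, b) for a, b in all_pairs[:k]])
            edges = set(net.edges)
            assert prev <= edges
            prev = edges


class TestTopologyReport:
    def test_four_cycle(self):
        rep = sn.topology_report(nx.cycle_graph(4))
        assert rep.degree_histogram == {2: 4}
        assert rep.shortest_path_histogram == {1: 4, 2: 2}
        assert all(v == pytest.approx(1.0)
                   for v in rep.topological_coefficient.values())

    def test_path_betweenness(self):
        rep = sn.topology_report(nx.path_graph(3))
        assert rep.betweenness[1] == pytest.approx(1.0)
        assert rep.betweenness[0] == rep.betweenness[2] == 0.0

    def test_handshake_lemma(self):
        g = nx.gnp_random_graph(40, 0.1, seed=2)
        rep = sn.topology_report(g)
        assert sum(k * c for k, c in rep.degree_histogram.items()) == \
            2 * g.number_of_edges()

    def test_shortest_path_histogram_vs_bfs_oracle(self):
        """Path-length histograms equal a hand-rolled all-pairs BFS on
        random graphs up to 50 nodes, including disconnected ones."""
        rng = np.random.default_rng(3)
        for n, p in [(10, 0.3), (25, 0.15), (50, 0.08), (50, 0.02)]:
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            hist = Counter()
            for s in g.nodes:  # BFS oracle
                dist = {s: 0}
                dq = deque([s])
                while dq:
                    u = dq.popleft()
                    for v in g[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            dq.append(v)
                for t, d in dist.items():
                    if t > s:
                        hist[d] += 1
            rep = sn.topology_report(g)
            assert rep.shortest_path_histogram == dict(hist)

    def test_mean_degree_and_too_small_graph(self):
        rep = sn.topology_report(nx.complete_graph(5))
        assert rep.mean_degree == pytest.approx(4.0)
        with pytest.raises(ValidationError):
            sn.topology_report(nx.Graph([("a", "a")]))


class TestFitPowerLaw:
    def test_exact_quadratic_decay(self):
        hist = {k: int(round(1e12 * k ** -2.0)) for k in range(1, 51)}
        assert sn.fit_power_law(hist) == pytest.approx(2.0, abs=1e-6)

    def test_exact_shallow_decay(self):
        hist = {k: int(round(1e12 * k ** -0.872)) for k in range(1, 101)}
        assert sn.fit_power_law(hist) == pytest.approx(0.872, abs=1e-6)

    def test_uniform_histogram_is_flat(self):
        assert sn.fit_power_law({k: 100 for k in range(1, 11)}) == \
            pytest.approx(0.0, abs=1e-12)

    def test_mle_alternative_recovers_steep_exponent(self):
        hist = {k: int(round(1e9 * k ** -2.5)) for k in range(1, 200)}
        assert sn.fit_power_law(hist, method="mle") == pytest.approx(2.5, abs=0.05)

    def test_single_support_point_rejected(self):
        with pytest.raises(ValidationError):
            sn.fit_power_law({3: 100})


def _brute_steiner_optimum(g, terminals):
    """Minimum edges of any connected subgraph spanning the terminals."""
    others = [n for n in g.nodes if n not in terminals]
    best = None
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = set(terminals) | set(extra)
            sub = g.subgraph(nodes)
            if nx.is_connected(sub):
                size = len(nodes) - 1
                best = size if best is None else min(best, size)
        if best is not None:
            # supersets cannot produce fewer edges than |nodes|-1 at this r
            break
    return best


class TestSteinerSubnetwork:
    def test_path_endpoints(self):
        g = nx.path_graph(["a", "b", "c"])
        r = sn.steiner_subnetwork(g, {"a", "c"})
        assert r.tree_edges == {("a", "b"), ("b", "c")}
        assert r.steiner_nodes == {"b"}

    def test_star_leaves(self):
        g = nx.star_graph(["h", "x", "y", "z"])
        r = sn.steiner_subnetwork(g, {"x", "y"})
        assert r.tree_edges == {("h", "x"), ("h", "y")}
        assert r.steiner_nodes == {"h"}

    def test_tree_input_all_terminals_returns_itself(self):
        t = nx.random_labeled_tree(12, seed=4)
        r = sn.steiner_subnetwork(t, set(t.nodes))
        assert r.tree_edges == {tuple(sorted(e)) for e in t.edges}
        assert not r.steiner_nodes

    def test_missing_terminals_reported_or_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        r = sn.steiner_subnetwork(g, {"a", "zz"})
        assert r.terminals_missing == {"zz"}
        with pytest.raises(ValidationError, match="zz"):
            sn.steiner_subnetwork(g, {"zz"})

    def test_disconnected_terminals_give_forest(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.warns(UserWarning, match="connected components"):
            r = sn.steiner_subnetwork(g, {"a", "b", "c", "d"})
        assert r.tree_edges == {("a", "b"), ("c", "d")}

    def test_within_twice_optimum_on_atlas_graphs(self):
        """Heuristic tree size <= 2x the exhaustive Steiner optimum on every
        connected graph with <= 7 nodes (graph atlas), 3 terminals."""
        from networkx.generators.atlas import graph_atlas_g

        rng = np.random.default_rng(5)
        checked = 0
        for g in graph_atlas_g():
            if g.number_of_nodes() < 3 or not nx.is_connected(g):
                continue
            nodes = sorted(g.nodes)
            combos = list(itertools.combinations(nodes, 3))
            if len(combos) > 5:
                idx = rng.choice(len(combos), size=5, replace=False)
                combos = [combos[i] for i in sorted(idx)]
            for terms in combos:
                r = sn.steiner_subnetwork(g, set(terms))
                opt = _brute_steiner_optimum(g, set(terms))
                assert len(r.tree_edges) <= 2 * opt
                # sanity: the tree spans the terminals and is acyclic
                tg = nx.Graph(list(r.tree_edges))
                tg.add_nodes_from(terms)
                assert nx.is_connected(tg)
                assert tg.number_of_edges() == tg.number_of_nodes() - 1
                checked += 1
        assert checked > 2000


class TestFindHubs:
    def test_star_hub(self):
        g = nx.star_graph(4)
        assert sn.find_hubs(g, 1) == [0]

    def test_returns_exactly_n(self):
        g = nx.gnp_random_graph(30, 0.2, seed=6)
        assert len(sn.find_hubs(g, 5)) == 5

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(1 << 30)))
            got = sn.find_hubs(g, 10)
            oracle = sorted(g.nodes, key=lambda v: (-g.degree(v), str(v)))[:10]
            assert got == oracle
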