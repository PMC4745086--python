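"""Domain-interaction-based interactome inference and topology analysis.

Two proteins are predicted to interact when one carries a domain known to
interact with a domain of the other (a DOMINE-style domain-domain
interaction table provides that evidence). The resulting graph is simple
and undirected: no self-loops (a self-interacting domain connects two
*distinct* proteins that both carry it, but never a protein to itself) and
no parallel edges — multiple supporting domain pairs accumulate as edge
evidence instead.

Topology analysis covers the degree distribution with a power-law fit
P(k) ~ k^-b, the shortest-path-length distribution, per-node topological
coefficients and shortest-path betweenness. Seed-gene subnetworks are
extracted with the Takahashi-Matsuyama shortest-path Steiner heuristic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .annotation import DomainAssignment
from .errors import ValidationError
from .formats import DomainInteraction


@dataclass
class InteractionNetwork:
    """A simple undirected protein-protein interaction graph.

    Backed by a :class:`networkx.Graph`; each edge carries an ``evidence``
    attribute holding the set of (sorted) domain pairs that justify it.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def evidence(self, p: str, q: str) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges[p, q]["evidence"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    assignments: Sequence[DomainAssignment],
    ddis: Iterable[DomainInteraction],
) -> InteractionNetwork:
    """Join domain assignments against a DDI table.

    An edge (p, q), p != q, exists iff some domain of p and some domain of
    q form an unordered pair present in the DDI set. Nodes are proteins
    with at least one edge. Accessions must be unversioned on both sides
    (the readers in :mod:`snailnet.formats` guarantee this).
    """
    ddi_pairs = {tuple(sorted((d.domain_a, d.domain_b))) for d in ddis}
    by_domain: dict[str, set[str]] = {}
    for asg in assignments:
        for acc in asg.domains:
            by_domain.setdefault(acc, set()).add(asg.protein_id)

    g = nx.Graph()
    for a, b in ddi_pairs:
        prots_a = by_domain.get(a, ())
        prots_b = by_domain.get(b, ())
        for p in prots_a:
            for q in prots_b:
                if p == q:
                    continue
                if g.has_edge(p, q):
                    g.edges[p, q]["evidence"].add((a, b))
                else:
                    g.add_edge(p, q, evidence={(a, b)})
    return InteractionNetwork(g)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopologyReport:
    degree_histogram: dict[int, int]
    mean_degree: float
    powerlaw_b: float
    shortest_path_histogram: dict[int, int]
    topological_coefficient: dict[str, float]
    betweenness: dict[str, float]


def fit_power_law(degree_histogram: Mapping[int, int], method: str = "ls") -> float:
    """Estimate the exponent b of P(k) ~ k^-b from a degree histogram.

    ``ls`` (default) fits a least-squares line to log10 P(k) vs log10 k
    over all k >= 1 with nonzero count — the convention of the network
    topology tools this toolkit mirrors. ``mle`` instead maximises the
    discrete (zeta-normalised) power-law likelihood with k_min = 1.
    """
    ks = np.array(sorted(k for k, c in degree_histogram.items() if c > 0 and k >= 1))
    if ks.size < 2:
        raise ValidationError("power-law fit needs >= 2 distinct degrees")
    counts = np.array([degree_histogram[k] for k in ks], dtype=float)
    if method == "ls":
        p = counts / counts.sum()
        slope = np.polyfit(np.log10(ks), np.log10(p), 1)[0]
        return float(-slope)
    if method == "mle":
        n = counts.sum()
        sum_log_k = float((counts * np.log(ks)).sum())

        def nll(b: float) -> float:
            return b * sum_log_k + n * np.log(zeta(b, 1))

        res = minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
        return float(res.x)
    raise ValidationError(f"unknown power-law fit method '{method}'")


def _shortest_path_histogram(g: nx.Graph) -> dict[int, int]:
    hist: Counter[int] = Counter()
    for source, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if d > 0:
                hist[d] += 1
    # unordered reachable pairs counted once
    return {d: c // 2 for d, c in sorted(hist.items())}


def topological_coefficients(g: nx.Graph) -> dict[str, float]:
    """Per-node topological coefficient T_n.

    T_n averages J(n, m) over all nodes m (m != n) sharing at least one
    neighbor with n, divided by the degree of n, where J(n, m) is the
    number of shared neighbors plus one if n and m are directly linked.
    Nodes with degree 0, or with no co-neighbored partner, get 0.
    """
    neigh = {n: set(g[n]) for n in g.nodes}
    out: dict[str, float] = {}
    for n in g.nodes:
        k = len(neigh[n])
        if k == 0:
            out[n] = 0.0
            continue
        partners = set()
        for u in neigh[n]:
            partners.update(neigh[u])
        partners.discard(n)
        js = []
        for m in partners:
            shared = len(neigh[n] & neigh[m])
            if shared == 0:
                continue
            js.append(shared + (1 if m in neigh[n] else 0))
        out[n] = float(np.mean(js) / k) if js else 0.0
    return out


def topology_report(
    network: InteractionNetwork | nx.Graph,
    normalized_betweenness: bool = False,
) -> TopologyReport:
    """Compute degree, path-length, coefficient and betweenness summaries.

    Betweenness is reported as unnormalised shortest-path pair counts by
    default; ``normalized_betweenness`` divides by (n-1)(n-2)/2.
    """
    g = network.graph if isinstance(network, InteractionNetwork) else network
    if g.number_of_nodes() < 2:
        raise ValidationError("topology analysis needs >= 2 nodes")
    degrees = dict(g.degree())
    deg_hist = dict(sorted(Counter(degrees.values()).items()))
    assert sum(k * c for k, c in deg_hist.items()) == 2 * g.number_of_edges()
    mean_degree = 2 * g.number_of_edges() / g.number_of_nodes()
    try:
        b = fit_power_law(deg_hist)
    except ValidationError:
        b = float("nan")  # degenerate: a single distinct degree
    return TopologyReport(
        degree_histogram=deg_hist,
        mean_degree=mean_degree,
        powerlaw_b=b,
        shortest_path_histogram=_shortest_path_histogram(g),
        topological_coefficient=topological_coefficients(g),
        betweenness=nx.betweenness_centrality(g, normalized=normalized_betweenness),
    )


def find_hubs(network: InteractionNetwork | nx.Graph, n: int) -> list[str]:
    """Top-n nodes by degree, ties broken by node id ascending."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    g = network.graph if isinstance(network, InteractionNetwork) else network
    ranked = sorted(g.nodes, key=lambda v: (-g.degree(v), str(v)))
    return ranked[:n]


# ---------------------------------------------------------------------------
# Steiner subnetworks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubnetworkResult:
    terminals_found: frozenset[str]
    terminals_missing: frozenset[str]
    tree_edges: frozenset[tuple[str, str]]
    steiner_nodes: frozenset[str]
    hubs: tuple[str, ...]


def _bfs_attach(g: nx.Graph, tree_nodes: set[str], targets: set[str]):
    """Deterministic multi-source BFS returning the nearest target's path.

    Ties are resolved by (distance, node id); within a BFS level, parents
    are assigned in sorted node order, so the extracted path is unique.
    """
    parent: dict[str, str | None] = {v: None for v in tree_nodes}
    dist = {v: 0 for v in tree_nodes}
    frontier = sorted(tree_nodes)
    found: str | None = None
    while frontier and found is None:
        nxt = []
        for u in frontier:
            for v in sorted(g[u], key=str):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    nxt.append(v)
        hit = sorted(v for v in nxt if v in targets)
        if hit:
            found = hit[0]
        frontier = sorted(nxt)
    if found is None:
        return None
    path = [found]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return list(reversed(path))  # starts inside the tree


def steiner_subnetwork(
    network: InteractionNetwork | nx.Graph,
    terminals: Iterable[str],
    n_hubs: int = 5,
) -> SubnetworkResult:
    """Extract a minimal subnetwork connecting seed genes by shortest paths.

    Uses the Takahashi-Matsuyama heuristic with unit edge weights: the tree
    is seeded with the smallest-id terminal and repeatedly extended by the
    shortest path to the nearest unconnected terminal. Terminals absent
    from the network are dropped and reported; terminals split across
    connected components yield one tree per component (a forest), with a
    warning. Hubs are the tree's nodes ranked by their degree in the parent
    network.
    """
    g = network.graph if isinstance(network, InteractionNetwork) else network
    terms = set(terminals)
    if not terms:
        raise ValidationError("terminal set is empty")
    found = {t for t in terms if t in g}
    missing = terms - found
    if not found:
        raise ValidationError(
            f"no terminal present in the network; missing: {sorted(missing)}"
        )

    groups: dict[str, set[str]] = {}
    comp_of = {}
    for comp in nx.connected_components(g):
        members = found & comp
        if members:
            rep = min(members)
            groups[rep] = members
    if len(groups) > 1:
        warnings.warn(
            f"terminals span {len(groups)} connected components; "
            "returning a Steiner forest",
            stacklevel=2,
        )

    tree_edges: set[tuple[str, str]] = set()
    tree_nodes: set[str] = set()
    for rep in sorted(groups):
        members = groups[rep]
        comp_tree = {rep}
        remaining = set(members) - comp_tree
        while remaining:
            path = _bfs_attach(g, comp_tree, remaining)
            assert path is not None  # same component by construction
            for u, v in zip(path, path[1:]):
                tree_edges.add(tuple(sorted((u, v))))
            comp_tree.update(path)
            remaining -= comp_tree
        tree_nodes.update(comp_tree)

    hubs = sorted(tree_nodes, key=lambda v: (-g.degree(v), str(v)))[:n_hubs]
    return SubnetworkResult(
        terminals_found=frozenset(found),
        terminals_missing=frozenset(missing),
        tree_edges=frozenset(tree_edges),
        steiner_nodes=frozenset(tree_nodes - found),
        hubs=tuple(hubs),
    )
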