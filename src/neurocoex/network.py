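"""Thresholded co-expression graphs and degree-preserving clustering nulls.

A correlation matrix is turned into a simple undirected graph by keeping
gene pairs whose Pearson R strictly exceeds a cutoff (signed by default; an
absolute-value mode is available). The cliquishness of the graph is measured
by the Watts–Strogatz local clustering coefficient and compared against an
ensemble of random graphs with exactly the observed degree sequence,
generated by double-edge-swap rewiring. A chi-square test asks whether edges
incident to a focal gene set connect within the set more often than random
partner choice predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from neurocoex.coexpression import CorrelationMatrix

__all__ = [
    "build_threshold_graph",
    "local_clustering",
    "mean_clustering",
    "rewire_preserving_degrees",
    "degree_preserving_null",
    "threshold_sweep",
    "edge_composition_test",
    "ClusteringNullResult",
    "EdgeCompositionResult",
]


def build_threshold_graph(
    cm: CorrelationMatrix,
    threshold: float,
    focal_set=None,
    scope: str = "within_set",
    absolute: bool = False,
) -> nx.Graph:
    """Graph of gene pairs with correlation strictly above ``threshold``.

    ``scope='within_set'`` keeps only edges with both endpoints in
    ``focal_set`` (the set-internal network); ``scope='incident'`` keeps
    every edge with at least one focal endpoint. With ``focal_set=None`` all
    supra-threshold edges are kept. Isolated nodes are dropped; each node
    carries an ``in_focal`` label and each edge its correlation.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if scope not in ("within_set", "incident"):
        raise ValueError(f"scope must be 'within_set' or 'incident', got {scope!r}")
    r = np.abs(cm.R) if absolute else cm.R
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(np.triu(r > threshold, k=1))
    focal = frozenset(focal_set) if focal_set is not None else None
    g = nx.Graph()
    g.graph["threshold"] = threshold
    ids = cm.gene_ids
    for i, j in zip(ii, jj):
        a, b = ids[i], ids[j]
        if focal is not None:
            a_in, b_in = a in focal, b in focal
            if scope == "within_set" and not (a_in and b_in):
                continue
            if scope == "incident" and not (a_in or b_in):
                continue
        g.add_edge(a, b, r=float(cm.R[i, j]))
    for node in g.nodes:
        g.nodes[node]["in_focal"] = focal is None or node in focal
    return g


def local_clustering(g: nx.Graph, node):
    """Watts–Strogatz local clustering coefficient of one node.

    The fraction of realized edges among all pairs of immediate neighbors:
    C = 2·T / (k(k−1)) for degree k ≥ 2, where T counts edges between
    neighbors. Nodes of degree < 2 return ``None`` (undefined) and are
    excluded from network means.
    """
    if node not in g:
        raise KeyError(f"node {node!r} not in graph")
    if g.degree(node) < 2:
        return None
    return nx.clustering(g, node)


def mean_clustering(g: nx.Graph) -> float:
    """Mean local clustering over nodes of degree ≥ 2 (NaN if none)."""
    nodes = [n for n in g.nodes if g.degree(n) >= 2]
    if not nodes:
        return float("nan")
    c = nx.clustering(g, nodes)
    return float(np.mean(list(c.values())))


def rewire_preserving_degrees(
    g: nx.Graph,
    rng: np.random.Generator,
    n_swaps: int | None = None,
    max_tries: int | None = None,
) -> nx.Graph:
    """Randomize a graph by double-edge swaps, preserving every degree.

    Repeatedly picks two edges (u,v), (x,y) and rewires them to (u,x),(v,y)
    or (u,y),(v,x), rejecting swaps that would create a self-loop or a
    duplicate edge. By default ``n_swaps`` = 10 × edge count successful swaps
    are attempted within a bounded number of tries. Graphs admitting no valid
    swap (e.g. a triangle or complete graph) are returned unchanged as a
    copy.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("graph has no edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * m
    if max_tries is None:
        max_tries = 100 * m + 1000
    edges = [tuple(e) for e in g.edges()]
    adj: dict = {n: set(g.neighbors(n)) for n in g.nodes}
    swaps = tries = 0
    while swaps < n_swaps and tries < max_tries:
        tries += 1
        e1, e2 = rng.integers(0, m), rng.integers(0, m)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u,x) and (v,y)
        if u == x or v == y:
            continue
        if x in adj[u] or y in adj[v]:
            continue
        adj[u].discard(v); adj[v].discard(u)
        adj[x].discard(y); adj[y].discard(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        edges[e1] = (u, x)
        edges[e2] = (v, y)
        swaps += 1
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from(edges)
    return out


@dataclass
class ClusteringNullResult:
    """Observed mean clustering against a degree-preserving null ensemble."""

    observed_mean_c: float
    null_means: np.ndarray
    ratio: float
    p_empirical: float
    n_networks: int
    seed: int | None = None


def degree_preserving_null(
    g: nx.Graph, n_networks: int = 10_000, seed: int | np.random.Generator = 0
) -> ClusteringNullResult:
    """Compare mean clustering against degree-preserving random rewirings.

    Each null network is an independent double-edge-swap randomization of
    the observed graph; its degree sequence is asserted identical on every
    draw. The ratio is observed / mean(null means) and the p-value the
    add-one upper-tail estimate.
    """
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = mean_clustering(g)
    deg = sorted(d for _, d in g.degree())
    null_means = np.empty(n_networks)
    for t in range(n_networks):
        h = rewire_preserving_degrees(g, rng)
        if sorted(d for _, d in h.degree()) != deg:
            raise AssertionError("rewiring altered the degree sequence")
        null_means[t] = mean_clustering(h)
    null_mean = float(np.nanmean(null_means))
    ratio = observed / null_mean if null_mean > 0 else float("inf")
    p = (1 + int(np.sum(null_means >= observed))) / (1 + n_networks)
    return ClusteringNullResult(
        observed_mean_c=float(observed),
        null_means=null_means,
        ratio=float(ratio),
        p_empirical=float(p),
        n_networks=int(n_networks),
        seed=seed if isinstance(seed, int) else None,
    )


def threshold_sweep(
    cm: CorrelationMatrix,
    thresholds,
    focal_set,
    n_networks: int = 1000,
    seed: int = 0,
    scope: str = "within_set",
    absolute: bool = False,
) -> list[dict]:
    """Clustering-vs-null ratio across a range of correlation cutoffs.

    Returns one record per threshold with the graph size, observed mean
    clustering, null mean, ratio, and empirical p; thresholds whose graphs
    are empty (or have no node of degree ≥ 2) are reported with
    ``ratio=None``.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rng = np.random.default_rng(seed)
    records = []
    for thr in thresholds:
        g = build_threshold_graph(cm, thr, focal_set, scope=scope, absolute=absolute)
        rec = {
            "threshold": thr,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "observed_c": None,
            "null_mean_c": None,
            "ratio": None,
            "p_empirical": None,
        }
        if g.number_of_edges() > 0 and not np.isnan(mean_clustering(g)):
            res = degree_preserving_null(g, n_networks=n_networks, seed=rng)
            rec.update(
                observed_c=res.observed_mean_c,
                null_mean_c=float(np.nanmean(res.null_means)),
                ratio=res.ratio,
                p_empirical=res.p_empirical,
            )
        records.append(rec)
    return records


@dataclass
class EdgeCompositionResult:
    """Within-set vs cross-set composition of edges incident to a focal set."""

    n_within: int
    n_incident: int
    expected_fraction: float
    chi_square: float
    p_value: float


def edge_composition_test(g: nx.Graph, focal_set) -> EdgeCompositionResult:
    """Chi-square test for excess within-set edges among incident edges.

    ``g`` must contain the edges incident to the focal set (scope
    ``incident``). Under random partner choice among the graph's nodes, an
    incident edge is within-set with probability (f−1)/(n−1) where f counts
    focal nodes present and n all nodes. The 1-df chi-square compares the
    observed within/cross split to that expectation (no continuity
    correction).
    """
    focal = frozenset(focal_set)
    incident = [e for e in g.edges if e[0] in focal or e[1] in focal]
    n_incident = len(incident)
    if n_incident == 0:
        raise ValueError("no edges incident to the focal set")
    n_within = sum(1 for a, b in incident if a in focal and b in focal)
    n_nodes = g.number_of_nodes()
    n_focal = sum(1 for n in g.nodes if n in focal)
    if n_nodes < 2:
        raise ValueError("graph too small for a composition test")
    f = (n_focal - 1) / (n_nodes - 1)
    exp_within = n_incident * f
    exp_cross = n_incident * (1 - f)
    if exp_within == 0 or exp_cross == 0:
        raise ValueError("degenerate partition: an expected cell count is zero")
    chi2 = (n_within - exp_within) ** 2 / exp_within + (
        (n_incident - n_within) - exp_cross
    ) ** 2 / exp_cross
    p = float(stats.chi2.sf(chi2, df=1))
    return EdgeCompositionResult(
        n_within=int(n_within),
        n_incident=int(n_incident),
        expected_fraction=float(f),
        chi_square=float(chi2),
        p_value=p,
    )
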