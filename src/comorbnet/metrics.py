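"""Structural metrics, PageRank importance, node-removal experiments, and
abundant-connection comparison between subgroup networks.

Betweenness is computed on the unweighted thresholded graph and left
unnormalized (raw shortest-path counts). PageRank treats each undirected edge
as two directed edges with transition probability proportional to the cosine
weight; damping 0.85.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .network import ComorbidityNetwork

__all__ = [
    "NetworkSummary",
    "EdgeComparison",
    "EdgeStatus",
    "EdgeMode",
    "summarize_network",
    "pagerank_importance",
    "remove_top_nodes",
    "remove_nodes",
    "abundant_connections",
]


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return math.nan, math.nan, math.nan
    return (float(np.median(arr)),
            float(np.percentile(arr, 25)), float(np.percentile(arr, 75)))


@dataclass
class NetworkSummary:
    node_count: int
    edge_count: int
    density: float
    mean_degree: float
    degree_median: float
    degree_iqr: tuple[float, float]
    neighbor_degree_median: float
    neighbor_degree_iqr: tuple[float, float]
    degree: dict[str, int]
    avg_neighbor_degree: dict[str, float]
    betweenness: dict[str, float]
    pagerank: dict[str, float]


def summarize_network(net: ComorbidityNetwork) -> NetworkSummary:
    """Density, degree, average neighbor degree, betweenness, PageRank.

    Density = 2E / (N(N-1)): the share of realized connections among all
    potential ones. Average neighbor degree is reported as NaN for isolated
    nodes. Mean degree 2E/N is reported alongside the median because summary
    tables in this literature sometimes print one under the other's name.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if n == 1:
        raise ValueError("density undefined for a single-node network")
    e = g.number_of_edges()
    degree = {v: d for v, d in g.degree()}
    nbr = nx.average_neighbor_degree(g)
    avg_nbr = {v: (nbr[v] if degree[v] > 0 else math.nan) for v in g}
    btw = nx.betweenness_centrality(g, normalized=False)
    pr = pagerank_importance(net, top_k=0)[1]

    deg_med, deg_q1, deg_q3 = _median_iqr(degree.values())
    connected = [avg_nbr[v] for v in g if degree[v] > 0]
    nbr_med, nbr_q1, nbr_q3 = _median_iqr(connected)
    return NetworkSummary(
        node_count=n,
        edge_count=e,
        density=2 * e / (n * (n - 1)),
        mean_degree=2 * e / n,
        degree_median=deg_med,
        degree_iqr=(deg_q1, deg_q3),
        neighbor_degree_median=nbr_med,
        neighbor_degree_iqr=(nbr_q1, nbr_q3),
        degree=degree,
        avg_neighbor_degree=avg_nbr,
        betweenness=btw,
        pagerank=pr,
    )


def pagerank_importance(net: ComorbidityNetwork, damping: float = 0.85,
                        top_k: int = 5) -> tuple[list[tuple[str, float]],
                                                 dict[str, float]]:
    """Weighted PageRank ranking; scores sum to 1.

    Each undirected edge acts as two directed edges whose transition
    probability is proportional to the cosine weight; isolated nodes receive
    uniform teleport mass. Ties in the top-k are broken lexicographically.
    Returns (top_k list, full score dict); ``top_k=0`` returns all scores.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return [], {}
    scores = nx.pagerank(g, alpha=damping, weight="weight",
                         tol=1e-9, max_iter=10_000)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:top_k] if top_k else ranked
    return top, scores


def remove_nodes(net: ComorbidityNetwork,
                 nodes: Sequence[str]) -> tuple[ComorbidityNetwork, float]:
    """Drop the named nodes; return the reduced network and the removed-edge
    share (fraction of original edges lost)."""
    drop = set(nodes)
    orig_edges = len(net.edges)
    kept = [p for p in net.edges if p.code_a not in drop and p.code_b not in drop]
    reduced = ComorbidityNetwork(
        {c: est for c, est in net.nodes.items() if c not in drop},
        kept, net.cutoff,
        {**net.provenance, "removed_nodes": sorted(drop)},
    )
    share = 0.0 if orig_edges == 0 else (orig_edges - len(kept)) / orig_edges
    return reduced, share


def remove_top_nodes(net: ComorbidityNetwork, by: str = "degree",
                     k: int = 5) -> tuple[ComorbidityNetwork, float, list[str]]:
    """Remove the k highest-ranked nodes by degree or betweenness."""
    if k >= len(net.nodes):
        raise ValueError("k must be smaller than the node count")
    summary = summarize_network(net)
    if by == "degree":
        ranking = summary.degree
    elif by == "betweenness":
        ranking = summary.betweenness
    else:
        raise ValueError(f"unknown ranking criterion {by!r}")
    top = [c for c, _ in sorted(ranking.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]
    reduced, share = remove_nodes(net, top)
    return reduced, share, top


class EdgeStatus(str, Enum):
    SHARED = "shared"
    ABUNDANT_IN_A = "abundant_in_a"
    ABUNDANT_IN_B = "abundant_in_b"


class EdgeMode(str, Enum):
    UNIQUE = "unique"      # edge present in exactly one subgroup network
    ENRICHED = "enriched"  # present in both, weight difference >= threshold
    COMMON = "common"      # present in both, weights within the threshold


@dataclass(frozen=True)
class EdgeComparison:
    code_a: str
    code_b: str
    cosine_in_a: Optional[float]
    cosine_in_b: Optional[float]
    status: EdgeStatus
    mode: EdgeMode


def abundant_connections(net_a: ComorbidityNetwork, net_b: ComorbidityNetwork,
                         threshold: float = 0.05) -> list[EdgeComparison]:
    """Classify every edge present in either subgroup network.

    An edge is an *abundant connection* of a subgroup when it is unique to that
    subgroup's network, or present in both but with cosine weight at least
    ``threshold`` higher there; otherwise it is shared. Both networks must be
    built over the same universe policy; node sets that disagree beyond
    subgroup-specific prevalence raise a mismatch error.
    """
    w_a = {(p.code_a, p.code_b): p.cosine for p in net_a.edges}
    w_b = {(p.code_a, p.code_b): p.cosine for p in net_b.edges}
    for key in ("alpha", "include_td"):
        pa, pb = net_a.provenance.get(key), net_b.provenance.get(key)
        if pa is not None and pb is not None and pa != pb:
            raise ValueError(f"networks built under different {key}: {pa} vs {pb}")
    ua = net_a.provenance.get("universe")
    ub = net_b.provenance.get("universe")
    if ua is not None and ub is not None and set(ua) != set(ub):
        offending = sorted(set(ua) ^ set(ub))
        raise ValueError(f"mismatched universes; offending codes: {offending}")
    out: list[EdgeComparison] = []
    for key in sorted(set(w_a) | set(w_b)):
        ca, cb = w_a.get(key), w_b.get(key)
        if ca is not None and cb is None:
            status, mode = EdgeStatus.ABUNDANT_IN_A, EdgeMode.UNIQUE
        elif ca is None and cb is not None:
            status, mode = EdgeStatus.ABUNDANT_IN_B, EdgeMode.UNIQUE
        elif ca - cb >= threshold:
            status, mode = EdgeStatus.ABUNDANT_IN_A, EdgeMode.ENRICHED
        elif cb - ca >= threshold:
            status, mode = EdgeStatus.ABUNDANT_IN_B, EdgeMode.ENRICHED
        else:
            status, mode = EdgeStatus.SHARED, EdgeMode.COMMON
        out.append(EdgeComparison(key[0], key[1], ca, cb, status, mode))
    return out
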