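"""Phenotypic comorbidity network construction.

Edges connect diseases that co-occur within hospitalization records. Pairwise
strength is the cosine index n_ab / sqrt(n_a * n_b); significance is judged on
the phi coefficient (Pearson correlation of the two binary disease indicators)
through the t transform t = r*sqrt((N-2)/(1-r^2)). The network keeps the K
strongest cosine edges, where K is the number of positively correlated,
significant pairs — so the cosine-thresholded network and the
Pearson-significance network have matched edge counts (up to ties at the
cutoff value).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .emr_io import Cohort, THYROID_CODES
from .filters import comorbidity_universe
from .prevalence import PrevalenceEstimate, prevalence_with_ci

__all__ = [
    "PairStatistics",
    "ComorbidityNetwork",
    "pair_counts",
    "cosine_index",
    "phi_coefficient",
    "t_statistic",
    "attach_statistics",
    "calibrate_cutoff",
    "build_pcn",
]


@dataclass
class PairStatistics:
    """Contingency counts and association statistics for one unordered pair."""

    code_a: str
    code_b: str
    N: int
    n_a: int
    n_b: int
    n_ab: int
    cosine: float = 0.0
    phi: float = 0.0
    t: float = 0.0
    p_value: float = 1.0
    significant: bool = False
    infinite_t: bool = False

    def __post_init__(self):
        if self.code_a > self.code_b:
            raise ValueError("pairs are stored with code_a < code_b")
        if self.n_ab > min(self.n_a, self.n_b):
            raise ValueError("n_ab cannot exceed either marginal")


@dataclass
class ComorbidityNetwork:
    nodes: dict[str, PrevalenceEstimate]
    edges: list[PairStatistics]
    cutoff: float
    provenance: dict = field(default_factory=dict)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for code, est in self.nodes.items():
            g.nodes[code]["prevalence"] = est.prevalence
        for p in self.edges:
            g.add_edge(p.code_a, p.code_b, weight=p.cosine, phi=p.phi, p=p.p_value)
        return g


def pair_counts(cohort: Cohort, universe: Sequence[str],
                include_td: bool = True) -> list[PairStatistics]:
    """Exact contingency counts for every unordered pair of universe codes.

    ``include_td`` adds the thyroid codes present in the cohort as extra nodes,
    since the networks contain the thyroid diseases themselves even though
    prevalence tables exclude them. Pairs where either code has a zero marginal
    are skipped rather than zero-filled.
    """
    codes = sorted(set(universe))
    if include_td:
        present_td = sorted(set(cohort.code_universe()) & THYROID_CODES)
        codes = sorted(set(codes) | set(present_td))
    if not codes:
        raise ValueError("empty code universe")
    idx = {c: i for i, c in enumerate(codes)}
    N = len(cohort.records)
    M = np.zeros((N, len(codes)), dtype=np.int8)
    for i, rec in enumerate(cohort.records):
        for c in rec.codes:
            j = idx.get(c)
            if j is not None:
                M[i, j] = 1
    joint = M.T.astype(np.int64) @ M.astype(np.int64)
    marg = np.diag(joint)
    pairs: list[PairStatistics] = []
    for a in range(len(codes)):
        if marg[a] == 0:
            continue
        for b in range(a + 1, len(codes)):
            if marg[b] == 0:
                continue
            pairs.append(PairStatistics(
                codes[a], codes[b], N, int(marg[a]), int(marg[b]), int(joint[a, b])
            ))
    return pairs


def cosine_index(n_ab: int, n_a: int, n_b: int) -> float:
    """Co-occurrence strength n_ab / sqrt(n_a * n_b), in [0, 1]."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("undefined cosine: zero marginal count")
    return n_ab / math.sqrt(n_a * n_b)


def phi_coefficient(N: int, n_a: int, n_b: int, n_ab: int) -> float:
    """Pearson correlation of the two binary indicators, from 2x2 counts:
    (N*n_ab - n_a*n_b) / sqrt(n_a*n_b*(N-n_a)*(N-n_b))."""
    if not (0 < n_a < N and 0 < n_b < N):
        raise ValueError("undefined correlation: degenerate marginal (0 or N)")
    return (N * n_ab - n_a * n_b) / math.sqrt(
        n_a * n_b * (N - n_a) * (N - n_b)
    )


def t_statistic(r: float, N: int) -> tuple[float, float, bool]:
    """t = r*sqrt((N-2)/(1-r^2)) with a two-tailed p from Student t(N-2).

    |r| = 1 yields an infinite t; by contract the p-value is 0 with the
    ``infinite_t`` flag set.
    """
    if N <= 2:
        raise ValueError("need N > 2 for the t transform")
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r), 0.0, True
    t = r * math.sqrt((N - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=N - 2)
    return t, p, False


def attach_statistics(pairs: list[PairStatistics],
                      alpha: float = 0.05) -> list[PairStatistics]:
    """Fill cosine/phi/t/p on raw pair counts; degenerate pairs are skipped."""
    out = []
    for p in pairs:
        if not (0 < p.n_a < p.N and 0 < p.n_b < p.N):
            continue  # a code carried by no one or everyone: correlation undefined
        p.cosine = cosine_index(p.n_ab, p.n_a, p.n_b)
        p.phi = phi_coefficient(p.N, p.n_a, p.n_b, p.n_ab)
        p.t, p.p_value, p.infinite_t = t_statistic(p.phi, p.N)
        p.significant = p.phi > 0 and p.p_value < alpha
        out.append(p)
    return out


def calibrate_cutoff(pairs: list[PairStatistics],
                     alpha: float = 0.05) -> tuple[float, int]:
    """Cosine cutoff matching the count of significant positive correlations.

    K = number of pairs with phi > 0 and p < alpha (only positive correlations
    count: edges represent coexistence, not avoidance). The cutoff is the K-th
    largest cosine over all pairs; ties at the cutoff are included. K = 0 gives
    an infinite cutoff and an empty edge set.
    """
    K = sum(1 for p in pairs if p.phi > 0 and p.p_value < alpha)
    if K == 0:
        return math.inf, 0
    cosines = sorted((p.cosine for p in pairs), reverse=True)
    return cosines[K - 1], K


def build_pcn(cohort: Cohort, universe: Optional[Sequence[str]] = None,
              include_td: bool = True, alpha: float = 0.05,
              label: str = "") -> ComorbidityNetwork:
    """Construct the comorbidity network for a (sub)cohort.

    Nodes are the surviving diseases (plus thyroid codes when ``include_td``),
    each carrying its prevalence estimate; edges are the pairs whose cosine
    index reaches the calibrated cutoff. Deterministic given the inputs.
    """
    if len(cohort.records) < 3:
        warnings.warn(f"cohort {label or cohort.label!r} has < 3 records; "
                      "returning a degenerate network")
        nodes = {
            c: prevalence_with_ci(n, max(len(cohort.records), 1), code=c)
            for c, n in cohort.prevalence_counts().items()
        }
        return ComorbidityNetwork(nodes, [], math.inf,
                                  {"label": label or cohort.label, "alpha": alpha})
    if universe is None:
        universe = comorbidity_universe(cohort)
    pairs = attach_statistics(pair_counts(cohort, universe, include_td), alpha)
    cutoff, K = calibrate_cutoff(pairs, alpha)
    edges = [p for p in pairs if p.cosine >= cutoff and p.cosine > 0]

    N = len(cohort.records)
    counts = cohort.prevalence_counts()
    node_codes = sorted(set(universe) | (
        set(counts) & THYROID_CODES if include_td else set()
    ))
    nodes = {
        c: prevalence_with_ci(counts.get(c, 0), N, code=c)
        for c in node_codes if counts.get(c, 0) > 0
    }
    provenance = {
        "label": label or cohort.label,
        "alpha": alpha,
        "include_td": include_td,
        "universe": tuple(sorted(universe)),
        "N": N,
        "significant_pairs": K,
        "tie_expanded": len(edges) != K,
    }
    return ComorbidityNetwork(nodes, edges, cutoff, provenance)
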