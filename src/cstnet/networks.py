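"""Signed, significance-filtered microbial co-occurrence networks.

Every pair of sufficiently prevalent species is tested for monotone
association with Kendall's tau-b (tie-corrected); p-values are adjusted
across all tested pairs with Benjamini-Hochberg and pairs at q <= alpha
become edges, signed by the direction of the correlation.  Community
substructure ("modularity clusters") is found by greedy modularity
maximization on |tau| weights, and keystone taxa are ranked by degree.

Spearman's rho is available as an alternative correlation engine since
both conventions are common for abundance co-occurrence screens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceNetwork",
    "NetworkSummary",
    "kendall_tau",
    "build_network",
    "network_summary",
    "modularity_clusters",
    "keystone_taxa",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected taxon graph with signed, significance-filtered edges.

    Node attributes: ``mean_abundance``, ``degree``, ``module_id`` (after
    modularity detection).  Edge attributes: ``tau`` (the rank correlation,
    whatever the engine), raw ``p``, adjusted ``q``, ``sign`` and
    ``weight`` = |tau| used for modularity.
    """

    graph: nx.Graph
    alpha: float
    correction: str
    method: str
    n_samples: int
    n_pairs_tested: int
    modularity_q: float | None = None


@dataclass
class NetworkSummary:
    n_edges: int
    n_positive: int
    n_negative: int
    pct_positive: float
    n_modules: int
    modularity_q: float
    top_degree_taxa: list


def _tie_term(values: np.ndarray, func) -> float:
    """Sum func(t) over the tie-group sizes t of a vector."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts[counts > 1]
    return float(func(counts).sum()) if counts.size else 0.0


def _tau_b_asymptotic_p(num: float, n: int, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided normal-approximation p for C - D with tie corrections.

    Uses the classical tie-corrected null variance of C - D and a
    continuity correction of 1 on |C - D|.
    """
    tx = _tie_term(x, lambda t: t * (t - 1) * (2 * t + 5))
    ty = _tie_term(y, lambda t: t * (t - 1) * (2 * t + 5))
    x1 = _tie_term(x, lambda t: t * (t - 1))
    y1 = _tie_term(y, lambda t: t * (t - 1))
    x2 = _tie_term(x, lambda t: t * (t - 1) * (t - 2))
    y2 = _tie_term(y, lambda t: t * (t - 1) * (t - 2))
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - tx - ty) / 18.0
    var += x1 * y1 / (2.0 * n * (n - 1))
    if n > 2:
        var += x2 * y2 / (9.0 * n * (n - 1) * (n - 2))
    if var <= 0:
        return 1.0
    z = max(abs(num) - 1.0, 0.0) / math.sqrt(var)
    return float(2.0 * special.ndtr(-z))


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D count concordant
    and discordant pairs and n1, n2 the tied pairs within x and y.  The
    p-value is exact (null permutation distribution) for n <= 10 without
    ties, otherwise a normal approximation with continuity correction.
    A vector that is entirely tied leaves tau undefined: (nan, nan) is
    returned and such pairs are excluded upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return (float("nan"), float("nan"))
    n0 = n * (n - 1) // 2
    n1 = _tie_term(x, lambda t: t * (t - 1) / 2)
    n2 = _tie_term(y, lambda t: t * (t - 1) / 2)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    num = float((sx * sy).sum()) / 2.0  # C - D
    tau = num / math.sqrt((n0 - n1) * (n0 - n2))
    no_ties = n1 == 0 and n2 == 0
    if n <= 10 and no_ties:
        _, p = stats.kendalltau(x, y, variant="b", method="exact")
        return (float(tau), float(p))
    return (float(tau), _tau_b_asymptotic_p(num, n, x, y))


def _pairwise_kendall(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs tau-b and asymptotic p over the columns of ``values``.

    The C - D numerators for every column pair come from one matrix product
    of the stacked pairwise sign patterns, which is exact (sign products are
    integers) and fast for a few hundred taxa.  p-values use the same
    tie-corrected normal approximation as :func:`kendall_tau`.
    """
    n, p = values.shape
    iu, ju = np.triu_indices(n, k=1)
    signs = np.sign(values[iu, :] - values[ju, :]).astype(np.float64)  # pairs x p
    num = signs.T @ signs  # (C - D) per column pair
    n0 = n * (n - 1) / 2.0

    # per-column tie statistics feed both the tau-b denominator and the
    # tie-corrected null variance of C - D
    t1 = np.empty(p)   # sum t(t-1)/2
    tv = np.empty(p)   # sum t(t-1)(2t+5)
    t2 = np.empty(p)   # sum t(t-1)(t-2)
    for j in range(p):
        _, counts = np.unique(values[:, j], return_counts=True)
        c = counts[counts > 1].astype(float)
        t1[j] = (c * (c - 1) / 2).sum()
        tv[j] = (c * (c - 1) * (2 * c + 5)).sum()
        t2[j] = (c * (c - 1) * (c - 2)).sum()

    denom = np.sqrt(np.outer(n0 - t1, n0 - t1))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, num / denom, np.nan)

    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - tv[:, None] - tv[None, :]) / 18.0
    var += np.outer(t1 * 2, t1 * 2) / (2.0 * n * (n - 1))  # t1*2 = sum t(t-1)
    if n > 2:
        var += np.outer(t2, t2) / (9.0 * n * (n - 1) * (n - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.maximum(np.abs(num) - 1.0, 0.0) / np.sqrt(var)
    pvals = 2.0 * special.ndtr(-z)
    pvals = np.where(var > 0, pvals, 1.0)
    pvals = np.where(denom > 0, pvals, np.nan)
    np.fill_diagonal(tau, 1.0)
    np.fill_diagonal(pvals, 0.0)
    return tau, pvals


def build_network(
    table: AbundanceTable,
    min_prevalence: float = 0.2,
    alpha: float = 0.05,
    correction: str = "bh",
    method: str = "kendall",
) -> CooccurrenceNetwork:
    """Screen all species pairs for significant rank correlation.

    Species present (abundance > 0) in at least ``min_prevalence`` of the
    samples are nodes.  All node pairs are tested; with
    ``correction='bh'`` the p-values are Benjamini-Hochberg adjusted across
    every tested pair and edges keep q <= alpha (``'none'`` filters on the
    raw p instead, with q = p recorded).  Pairs whose correlation is
    undefined (a fully tied species) are excluded from testing.
    """
    n = table.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples to build a network")
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    present_frac = (table.values > 0).mean(axis=0)
    keep = present_frac >= min_prevalence
    species = [s for s, k in zip(table.species_ids, keep) if k]
    if len(species) < 2:
        raise ValueError("fewer than 2 species pass the prevalence filter")
    values = table.data[species].to_numpy(dtype=float)

    if method == "kendall":
        tau, pvals = _pairwise_kendall(values)
    elif method == "spearman":
        tau, pvals = stats.spearmanr(values)
        tau = np.atleast_2d(tau)
        pvals = np.atleast_2d(pvals)
    else:
        raise ValueError(f"unknown method {method!r}")

    p_count = len(species)
    iu, ju = np.triu_indices(p_count, k=1)
    raw_p = pvals[iu, ju]
    raw_tau = tau[iu, ju]
    defined = ~np.isnan(raw_tau)
    n_tested = int(defined.sum())
    q = np.full(raw_p.shape, np.nan)
    if n_tested:
        if correction == "bh":
            q[defined] = multipletests(raw_p[defined], method="fdr_bh")[1]
        else:
            q[defined] = raw_p[defined]

    graph = nx.Graph()
    means = values.mean(axis=0)
    for name, mean_ab in zip(species, means):
        graph.add_node(name, mean_abundance=float(mean_ab))
    keep_edge = defined & (q <= alpha) & (raw_tau != 0)
    for idx in np.flatnonzero(keep_edge):
        a, b = species[iu[idx]], species[ju[idx]]
        t = float(raw_tau[idx])
        graph.add_edge(
            a, b,
            tau=t, p=float(raw_p[idx]), q=float(q[idx]),
            sign="positive" if t > 0 else "negative",
            weight=abs(t),
        )
    for name in graph.nodes:
        graph.nodes[name]["degree"] = graph.degree(name)
    return CooccurrenceNetwork(
        graph=graph, alpha=alpha, correction=correction, method=method,
        n_samples=n, n_pairs_tested=n_tested,
    )


def modularity_clusters(net: CooccurrenceNetwork, seed: int = 0) -> tuple[dict, float]:
    """Greedy modularity maximization on |tau| edge weights.

    Deterministic: the greedy agglomeration involves no randomness, so the
    seed only namespaces the API for interchangeable backends.  Nodes of an
    edgeless graph each get their own module and Q = 0.  Module ids are
    contiguous integers ordered by decreasing module size; assignments are
    also written onto the node attribute ``module_id``.
    """
    graph = net.graph
    if graph.number_of_edges() == 0:
        assignment = {node: i for i, node in enumerate(sorted(graph.nodes))}
        q = 0.0
    else:
        communities = greedy_modularity_communities(graph, weight="weight")
        communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
        assignment = {node: i for i, comm in enumerate(communities) for node in comm}
        q = modularity(graph, communities, weight="weight")
        isolated = [v for v in graph.nodes if v not in assignment]
        for i, v in enumerate(sorted(isolated)):
            assignment[v] = len(communities) + i
    nx.set_node_attributes(graph, assignment, "module_id")
    net.modularity_q = float(q)
    return assignment, float(q)


def network_summary(net: CooccurrenceNetwork) -> NetworkSummary:
    """Edge counts, percent positive, module count and top-degree taxa."""
    graph = net.graph
    signs = [d["sign"] for _, _, d in graph.edges(data=True)]
    n_edges = len(signs)
    n_pos = sum(s == "positive" for s in signs)
    n_neg = n_edges - n_pos
    pct_pos = 100.0 * n_pos / n_edges if n_edges else 0.0
    if net.modularity_q is None:
        modularity_clusters(net)
    modules = nx.get_node_attributes(graph, "module_id")
    n_modules = len(set(modules.values())) if modules else 0
    by_degree = sorted(graph.nodes, key=lambda v: (-graph.degree(v), str(v)))
    return NetworkSummary(
        n_edges=n_edges, n_positive=n_pos, n_negative=n_neg,
        pct_positive=pct_pos, n_modules=n_modules,
        modularity_q=float(net.modularity_q), top_degree_taxa=by_degree,
    )


def keystone_taxa(net: CooccurrenceNetwork, top_n: int = 10) -> list:
    """Most-connected taxa: degree desc, then mean abundance desc, then name."""
    graph = net.graph
    if top_n > graph.number_of_nodes():
        logger.warning(
            "top_n=%d exceeds node count %d; returning full ordering",
            top_n, graph.number_of_nodes(),
        )
        top_n = graph.number_of_nodes()
    ranked = sorted(
        graph.nodes,
        key=lambda v: (-graph.degree(v), -graph.nodes[v].get("mean_abundance", 0.0), str(v)),
    )
    return ranked[:top_n]
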