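"""Species co-occurrence networks per group-timepoint and their differences.

A network for one set of samples is built by (1) filtering species to a
minimum prevalence, (2) CLR-transforming the relative abundances, (3)
computing all pairwise Spearman correlations, and (4) keeping an edge when
|rho| >= a threshold AND the BH-adjusted correlation p-value is below
alpha. Edges carry the correlation and its sign; modularity is computed on
the unsigned skeleton while the positive-edge fraction keeps the signs.

Differential network analysis contrasts a property (edge count, density,
mean degree, transitivity, modularity, ...) between the pre- and
post-treatment networks of one arm; the null distribution comes from
swapping each subject's pre/post labels with probability 1/2 and
rebuilding both networks per permutation, a subject-respecting exchange
that preserves the paired structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceTable, CohortMetadata, PairedDesign, build_paired_design
from .differential import bh_adjust
from .diversity import clr_transform

__all__ = [
    "build_network",
    "network_properties",
    "NetworkSummary",
    "differential_network",
    "NETWORK_PROPERTIES",
]

NETWORK_PROPERTIES = (
    "n_edges", "density", "connectivity", "clustering_coefficient",
    "modularity", "positive_edge_fraction",
)


def build_network(
    table: AbundanceTable,
    sample_subset: list[str] | None = None,
    min_prevalence: float = 0.2,
    rho_threshold: float = 0.3,
    alpha: float = 0.05,
    pseudocount: float | str = "half-min",
) -> tuple[nx.Graph, pd.DataFrame]:
    """Build one co-occurrence network from a species table subset.

    Returns the graph (nodes = surviving species; edge attributes ``rho``,
    ``p_bh``, ``sign``) and the edge table. Prevalence is the fraction of
    subset samples in which a species is detected (> 0).
    """
    sub = table.subset_samples(sample_subset) if sample_subset is not None else table
    if sub.n_samples < 10:
        raise ValueError(f"need >= 10 samples to estimate correlations, got {sub.n_samples}")
    prevalence = (sub.values > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 features pass prevalence >= {min_prevalence} "
            f"({int(keep.sum())} of {sub.n_features})"
        )
    filtered = AbundanceTable(sub.data.loc[keep], kind=sub.kind)
    clr = clr_transform(filtered, pseudocount=pseudocount)
    X = clr.to_numpy(dtype=float)  # features x samples
    features = list(clr.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pval = stats.spearmanr(X, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    iu = np.triu_indices(len(features), k=1)
    p_flat = pval[iu]
    p_flat = np.where(np.isfinite(p_flat), p_flat, 1.0)
    p_bh = bh_adjust(p_flat)
    rho_flat = rho[iu]
    edges = []
    graph = nx.Graph()
    graph.add_nodes_from(features)
    for (i, j, r, pb) in zip(iu[0], iu[1], rho_flat, p_bh):
        if np.isfinite(r) and abs(r) >= rho_threshold and pb < alpha:
            a, b = features[i], features[j]
            sign = 1 if r > 0 else -1
            graph.add_edge(a, b, rho=float(r), p_bh=float(pb), sign=sign)
            edges.append({"feature_a": a, "feature_b": b, "rho": float(r),
                          "p_bh": float(pb), "sign": sign})
    edge_table = pd.DataFrame(edges, columns=["feature_a", "feature_b", "rho", "p_bh", "sign"])
    return graph, edge_table


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    connectivity: float            # mean node degree
    clustering_coefficient: float  # global transitivity
    modularity: float              # greedy partition, unsigned skeleton
    positive_edge_fraction: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "connectivity": self.connectivity,
            "clustering_coefficient": self.clustering_coefficient,
            "modularity": self.modularity,
            "positive_edge_fraction": self.positive_edge_fraction,
            "degenerate": self.degenerate,
        }


def network_properties(graph: nx.Graph) -> NetworkSummary:
    """Summary statistics of one co-occurrence network.

    density = 2E / (N(N-1)); connectivity = mean degree = 2E / N;
    clustering coefficient = global transitivity (3 * triangles /
    connected triples); modularity from greedy modularity maximisation on
    the unsigned graph (node order fixed by sorting for determinism). An
    edgeless graph returns zeros flagged degenerate.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    # relabel-free determinism: operate on a sorted-node copy
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes()))
    g.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in graph.edges()))
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if m == 0:
        return NetworkSummary(n, 0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    connectivity = 2.0 * m / n
    clustering = float(nx.transitivity(g))
    communities = nx.community.greedy_modularity_communities(g)
    modularity = float(nx.community.modularity(g, communities))
    signs = [d.get("sign", 1) for _, _, d in graph.edges(data=True)]
    pos_frac = float(np.mean([s > 0 for s in signs]))
    return NetworkSummary(n, m, density, connectivity, clustering, modularity, pos_frac)


def differential_network(
    table: AbundanceTable,
    meta: CohortMetadata,
    arm: str,
    post_day: int,
    property_list: tuple[str, ...] = NETWORK_PROPERTIES,
    n_perm: int = 99,
    seed: int | None = None,
    **network_kwargs,
) -> pd.DataFrame:
    """Permutation test of post-minus-pre network property changes.

    The observed delta of each property compares the arm's post-day and
    day-0 networks. The null swaps each subject's pre/post samples with
    probability 1/2, rebuilds both networks, and recomputes the deltas;
    ``p = (1 + #{|delta_perm| >= |delta_obs|}) / (1 + n_perm)``.
    """
    unknown = [p for p in property_list if p not in NETWORK_PROPERTIES]
    if unknown:
        raise ValueError(f"unknown properties {unknown}; choose from {NETWORK_PROPERTIES}")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation p; >= 99 recommended")
    design = build_paired_design(meta, post_day).for_arm(arm)
    if design.n_pairs == 0:
        raise ValueError(f"no pairs for arm {arm!r} at day {post_day}")
    pre_ids = np.array(design.pre_sample_ids())
    post_ids = np.array(design.post_sample_ids())

    def deltas_for(pre: np.ndarray, post: np.ndarray) -> dict[str, float]:
        g_pre, _ = build_network(table, list(pre), **network_kwargs)
        g_post, _ = build_network(table, list(post), **network_kwargs)
        s_pre = network_properties(g_pre).as_dict()
        s_post = network_properties(g_post).as_dict()
        return {p: float(s_post[p]) - float(s_pre[p]) for p in property_list}

    observed = deltas_for(pre_ids, post_ids)
    rng = np.random.default_rng(seed)
    exceed = {p: 0 for p in property_list}
    for _ in range(n_perm):
        swap = rng.random(design.n_pairs) < 0.5
        perm_pre = np.where(swap, post_ids, pre_ids)
        perm_post = np.where(swap, pre_ids, post_ids)
        perm_deltas = deltas_for(perm_pre, perm_post)
        for p in property_list:
            if abs(perm_deltas[p]) >= abs(observed[p]) - 1e-12:
                exceed[p] += 1
    rows = [
        {
            "property": p,
            "observed_delta": observed[p],
            "p_value": (1 + exceed[p]) / (1 + n_perm),
            "n_permutations": n_perm,
            "seed": seed,
        }
        for p in property_list
    ]
    return pd.DataFrame(rows)
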