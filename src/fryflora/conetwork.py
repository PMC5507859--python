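"""Thresholded co-abundance networks over the most abundant OTUs.

Edges connect OTU pairs whose per-sample relative abundances have a Spearman
rank correlation of at least ``rho_min`` (positive co-abundance only) with a
Bonferroni-corrected p-value at most ``alpha_adj``.  Correlations are
computed over all samples of the dataset; per-stage network views are
obtained by provenance labelling and node filtering, since the handful of
samples inside a single stage could never reach Bonferroni significance at
the published thresholds.

Raw p-values use the t approximation ``t = rho sqrt((n-2)/(1-rho^2))`` with
``n - 2`` degrees of freedom (two-tailed); the Bonferroni factor is the
number of candidate pairs ``k(k-1)/2``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "top_k_otus",
    "spearman_edges",
    "build_network",
    "provenance_labels",
    "NetworkStats",
    "network_stats",
    "export_network",
    "read_network",
]

logger = logging.getLogger(__name__)


def top_k_otus(rel: pd.DataFrame, k: int = 50) -> list[str]:
    """The k most abundant OTUs by mean relative abundance over all samples.

    Ties break by OTU identifier (ascending); if the table holds fewer than
    ``k`` OTUs, all are returned.  The ranking is invariant to sample order.
    """
    means = rel.mean(axis=1)
    order = sorted(rel.index, key=lambda o: (-means[o], o))
    return order[: min(k, len(order))]


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p from the t approximation; exact 0 for |rho| = 1."""
    rho = np.clip(rho, -1.0, 1.0)
    p = np.zeros_like(rho)
    boundary = np.isclose(np.abs(rho), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p[~boundary] = 2.0 * stats.t.sf(np.abs(t[~boundary]), n - 2)
    p[boundary] = 0.0
    return np.minimum(p, 1.0)


def spearman_edges(rel: pd.DataFrame, rho_min: float = 0.9,
                   alpha_adj: float = 1e-4,
                   return_all: bool = False) -> pd.DataFrame:
    """Pairwise Spearman correlations with Bonferroni-thresholded retention.

    ``rel`` holds the candidate OTUs (rows) over the samples used for
    correlation (columns); at least 5 samples are required, since fewer can
    never reach any corrected significance.  Ties are handled by average
    ranks.  Pairs involving a constant abundance vector have an undefined
    correlation and are skipped with a log entry.

    Returns a frame with columns ``otu_a, otu_b, rho, p_raw, p_adj``; by
    default only retained edges (``rho >= rho_min`` and ``p_adj <= alpha_adj``).
    """
    otus = list(rel.index)
    n = rel.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples for corrected significance")
    k = len(otus)
    m = k * (k - 1) // 2  # Bonferroni factor: number of candidate pairs
    ranks = np.apply_along_axis(stats.rankdata, 1, rel.to_numpy(dtype=float))
    constant = np.isclose(rel.to_numpy(dtype=float).std(axis=1), 0.0)
    with np.errstate(invalid="ignore"):
        rho_mat = np.corrcoef(ranks)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        if constant[i] or constant[j]:
            logger.info("skipping pair (%s, %s): constant abundance vector",
                        otus[i], otus[j])
            continue
        rho = float(rho_mat[i, j])
        p_raw = float(_spearman_p(np.array([rho]), n)[0])
        p_adj = min(1.0, p_raw * m)
        retained = rho >= rho_min and p_adj <= alpha_adj
        if return_all or retained:
            rows.append({"otu_a": otus[i], "otu_b": otus[j], "rho": rho,
                         "p_raw": p_raw, "p_adj": p_adj, "retained": retained})
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p_raw", "p_adj",
                                       "retained"])


def build_network(rel: pd.DataFrame, k: int = 50, rho_min: float = 0.9,
                  alpha_adj: float = 1e-4, taxonomy=None) -> nx.Graph:
    """Co-abundance network over the top-k OTUs of a relative-abundance table.

    Nodes are the k most abundant OTUs (taxon labels attached when a taxonomy
    is supplied); edges carry ``rho``, ``p_raw`` and ``p_adj``; node degrees
    are stored as attributes.  Network parameters live in ``G.graph``.
    """
    otus = top_k_otus(rel, k)
    edges = spearman_edges(rel.loc[otus], rho_min=rho_min, alpha_adj=alpha_adj)
    g = nx.Graph(k=len(otus), rho_min=rho_min, alpha_adj=alpha_adj,
                 n_samples=rel.shape[1],
                 bonferroni_factor=len(otus) * (len(otus) - 1) // 2)
    for otu in otus:
        label = taxonomy.label(otu) if taxonomy is not None else otu
        g.add_node(otu, taxon=label)
    for row in edges.itertuples():
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho),
                   p_raw=float(row.p_raw), p_adj=float(row.p_adj))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return g


def provenance_labels(network: nx.Graph, fry: pd.DataFrame,
                      reservoir: pd.DataFrame,
                      min_presence: float = 0.0) -> nx.Graph:
    """Label nodes by compartment provenance for one developmental stage.

    Each node becomes ``fry_only``, ``reservoir_only`` or ``shared`` using the
    presence rule (> ``min_presence`` in >= 1 sample); OTUs detected in
    neither compartment are dropped from the stage view.  Returns a labelled
    copy; the input graph is unchanged.
    """
    g = network.copy()
    fry_present = set(fry.index[(fry > min_presence).any(axis=1)])
    res_present = set(reservoir.index[(reservoir > min_presence).any(axis=1)])
    drop = []
    for node in g.nodes:
        in_fry, in_res = node in fry_present, node in res_present
        if in_fry and in_res:
            g.nodes[node]["provenance"] = "shared"
        elif in_fry:
            g.nodes[node]["provenance"] = "fry_only"
        elif in_res:
            g.nodes[node]["provenance"] = "reservoir_only"
        else:
            drop.append(node)
    g.remove_nodes_from(drop)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return g


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    mean_degree: float
    empty: bool = False


def network_stats(network: nx.Graph, provenance: str | None = None) -> NetworkStats:
    """Node count and mean degree, optionally restricted by provenance label.

    ``provenance=None`` summarizes every node; ``"fry_only"`` reproduces the
    published per-stage "taxa unique to the fry and their mean inter-taxa
    connections" statistic.  Degrees count all incident edges in the network.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if provenance is None:
        nodes = list(network.nodes)
    else:
        nodes = [n for n, d in network.nodes(data=True)
                 if d.get("provenance") == provenance]
    if not nodes:
        return NetworkStats(n_nodes=0, mean_degree=0.0, empty=True)
    degrees = [network.degree(n) for n in nodes]
    return NetworkStats(n_nodes=len(nodes), mean_degree=float(np.mean(degrees)))


def export_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML (Cytoscape-ready) or an edge-list TSV."""
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edge_list_tsv":
        rows = [
            {"otu_a": a, "otu_b": b, "rho": d.get("rho"), "p_raw": d.get("p_raw"),
             "p_adj": d.get("p_adj")}
            for a, b, d in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p_raw", "p_adj"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path) -> nx.Graph:
    """Round-trip companion of :func:`export_network` for GraphML files."""
    return nx.read_graphml(path)
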