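"""Degree and betweenness centrality on interaction networks.

Graphs are undirected and unweighted.  Betweenness is the Brandes
accumulation of pair dependencies sigma_st(v)/sigma_st; normalized
betweenness divides by (n−1)(n−2)/2, so values live in [0, 1].
Disconnected pairs contribute nothing.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd


def _as_graph(edges_or_graph) -> nx.Graph:
    if isinstance(edges_or_graph, nx.Graph):
        return edges_or_graph
    G = nx.Graph()
    for edge in edges_or_graph:
        a, b = edge[0], edge[1]
        if a != b:
            G.add_edge(a, b)
    return G


def betweenness_centrality(edges_or_graph, normalized: bool = True) -> dict:
    """Per-node betweenness; empty input gives an empty result."""
    G = _as_graph(edges_or_graph)
    return nx.betweenness_centrality(G, normalized=normalized)


def centrality_table(edges_or_graph, normalized: bool = True) -> pd.DataFrame:
    """Degree and betweenness per node — the two hub indicators."""
    G = _as_graph(edges_or_graph)
    bc = nx.betweenness_centrality(G, normalized=normalized)
    rows = [
        {"node_id": n, "degree": G.degree(n), "betweenness": bc[n]} for n in G.nodes
    ]
    return pd.DataFrame(rows, columns=["node_id", "degree", "betweenness"])


def rank_hubs(records: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top nodes by betweenness (descending), ties by degree then node id."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = records.sort_values(
        ["betweenness", "degree", "node_id"], ascending=[False, False, True]
    ).head(top_n).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df
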