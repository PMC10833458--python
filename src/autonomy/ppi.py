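"""Protein-protein interaction graphs, degree z-scores and hub extraction.

Starting from a per-protein enrichment table (intensity ratio and a
significance score), proteins are filtered (ratio >= 2, significance >= 20
by default, both inclusive), the induced subgraph of a STRING-style edge
list is built, and hubs are selected by the degree z-score
Z_d(v) = (deg(v) - mean(deg)) / sd_pop(deg). Edges are unweighted;
confidence scores may be thresholded at load but are never used as weights.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io import read_edge_list

logger = logging.getLogger(__name__)


def filter_proteins(table: pd.DataFrame, ratio_cut: float = 2.0,
                    sig_cut: float = 20.0, ratio_col: str = "ratio",
                    sig_col: str = "significance") -> set[str]:
    """Proteins with ratio >= ratio_cut and significance >= sig_cut (inclusive)."""
    for col in (ratio_col, sig_col):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in protein table")
    keep = table.index[(table[ratio_col] >= ratio_cut) & (table[sig_col] >= sig_cut)]
    selected = set(map(str, keep))
    if not selected:
        logger.warning("protein filter (ratio >= %g, significance >= %g) "
                       "selected no proteins", ratio_cut, sig_cut)
    return selected


def build_graph(proteins, edges, *, score_min: float | None = None) -> nx.Graph:
    """Induced undirected subgraph on ``proteins``.

    ``edges`` is a path to an edge-list file or an iterable of (a, b) pairs.
    Self-loops are dropped and duplicate/reversed edges merged; proteins
    with no interactions remain as isolated nodes.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "__fspath__"):
        edges = read_edge_list(edges, score_min=score_min)
    proteins = set(map(str, proteins))
    g = nx.Graph()
    g.add_nodes_from(sorted(proteins))
    for a, b in edges:
        if a == b:
            continue
        if a in proteins and b in proteins:
            g.add_edge(a, b)
    return g


def degree_zscores(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree and degree z-score (population sd).

    A constant-degree graph gets Z_d = 0 for every node by convention.
    Returns a DataFrame indexed by node with columns degree, zd.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    nodes = sorted(graph.nodes)
    deg = np.array([graph.degree[v] for v in nodes], dtype=float)
    sd = float(deg.std(ddof=0))
    zd = np.zeros_like(deg) if sd == 0.0 else (deg - deg.mean()) / sd
    return pd.DataFrame({"degree": deg.astype(int), "zd": zd}, index=nodes)


def select_hubs(graph: nx.Graph, zd_cut: float = 3.0) -> pd.DataFrame:
    """Nodes with Z_d >= zd_cut, sorted by degree descending then node id."""
    table = degree_zscores(graph)
    hubs = table[table["zd"] >= zd_cut].sort_index(kind="stable")
    return hubs.sort_values("degree", ascending=False, kind="stable")
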