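"""Hypergeometric pathway enrichment and the shared-protein pathway network.

A query protein set (e.g. the lesion-predominant cluster) is tested against a
gene-set collection with the upper-tail hypergeometric distribution on the
measured-proteome universe, BH-adjusted across all tested sets.  Retained
pathways become nodes of an undirected network: node size is the number of
dataset proteins in the pathway, and two pathways are connected iff their
dataset overlaps share proteins (edge weight = number shared).  Node
centralities (betweenness, closeness, degree, each normalized to [0, 1] per
connected component on the unweighted graph) rank pathways; the top-ranked
central pathways are the candidate target reservoirs.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParameterError
from .filtering import bh_adjust
from .io import GeneSetCollection

ENRICHMENT_COLUMNS = [
    "set_id",
    "overlap_count",
    "set_size",
    "query_size",
    "universe_size",
    "p",
    "q",
    "retained",
    "overlap_members",
]


def hypergeom_enrich(query, collection: GeneSetCollection, universe, fdr: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of ``query`` in each gene set.

    With population N = |universe|, successes K = |set ∩ universe|, draws
    n = |query| and observed overlap k, ``p = P(X >= k)``.  ``q`` is BH over
    all tested sets; ``retained`` flags ``q <= fdr``.  Sets are intersected
    with the universe before testing; sets disjoint from the universe are
    skipped.
    """
    query = {str(x).upper() for x in query}
    universe = {str(x).upper() for x in universe}
    if not query or not universe:
        raise ParameterError("query and universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ParameterError(f"query must be a subset of the universe (e.g. {extra})")
    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(collection):
        members = collection.members(set_id) & universe
        if not members:
            continue
        overlap = frozenset(members & query)
        k, K = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, k, K, n, N, min(p, 1.0), overlap))
    records = pd.DataFrame(
        rows,
        columns=["set_id", "overlap_count", "set_size", "query_size", "universe_size", "p", "overlap_members"],
    )
    records["q"] = bh_adjust(records["p"]) if len(records) else np.array([])
    records["retained"] = records["q"] <= fdr
    records = records.loc[:, ENRICHMENT_COLUMNS]
    return records.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)


def build_pathway_graph(records: pd.DataFrame) -> nx.Graph:
    """Shared-protein network over retained enrichment records.

    Nodes carry ``node_size`` (= overlap_count), ``overlap`` (frozenset of
    dataset proteins), ``p`` and ``q``; an edge joins two pathways iff their
    overlap members intersect, weighted by the intersection size.
    """
    graph = nx.Graph()
    kept = records.loc[records["retained"]] if "retained" in records.columns else records
    if not len(kept):
        warnings.warn("no retained enrichment records; pathway graph is empty")
        return graph
    for rec in kept.itertuples(index=False):
        graph.add_node(
            rec.set_id,
            node_size=int(rec.overlap_count),
            overlap=frozenset(rec.overlap_members),
            p=float(rec.p),
            q=float(rec.q),
        )
    for a, b in combinations(sorted(graph.nodes), 2):
        shared = graph.nodes[a]["overlap"] & graph.nodes[b]["overlap"]
        if shared:
            graph.add_edge(a, b, weight=len(shared))
    return graph


def node_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Betweenness, closeness and degree centrality, normalized per component.

    Betweenness uses pair normalization (n-1)(n-2)/2 within each connected
    component (0 for components with < 3 nodes); closeness is
    (n_comp - 1) / sum of distances within the component; degree is
    degree / (n_comp - 1).  Isolated nodes score 0 on all three.
    """
    rows = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        n = len(comp)
        if n < 2:
            for node in comp:
                rows[node] = (0.0, 0.0, 0.0)
            continue
        bet = (
            nx.betweenness_centrality(sub, normalized=True)
            if n >= 3
            else {node: 0.0 for node in comp}
        )
        clo = nx.closeness_centrality(sub, wf_improved=False)
        for node in comp:
            rows[node] = (bet[node], clo[node], sub.degree(node) / (n - 1))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["betweenness", "closeness", "degree"])
    frame.index.name = "node"
    return frame.sort_index()


def top_central_pathways(graph: nx.Graph, k: int = 3, centralities: pd.DataFrame | None = None) -> list:
    """Pathway ids ranked by betweenness (ties: closeness, degree, set id)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if graph.number_of_nodes() == 0:
        return []
    if centralities is None:
        centralities = node_centralities(graph)
    frame = centralities.reset_index()
    frame = frame.sort_values(
        ["betweenness", "closeness", "degree", "node"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    return list(frame["node"].head(k))
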