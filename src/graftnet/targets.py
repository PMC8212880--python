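"""Consensus central-protein calls within top-ranked pathways.

For each candidate pathway, the member proteins present in the interactome
induce a subgraph; every member gets the same three normalized centralities
used for pathway nodes (betweenness, closeness, degree) plus a dense rank per
centrality.  The three pairwise centrality comparisons are formalized as Borda
aggregation: the consensus target is the protein with the smallest sum of the
three ranks (ties broken by betweenness value, then protein id).  A protein
that strictly dominates on all three centralities always wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .enrichment import node_centralities
from .errors import DataError, ParameterError


@dataclass(frozen=True)
class TargetCall:
    pathway_id: str
    protein_id: str
    borda_score: int
    betweenness: float
    closeness: float
    degree: float
    tied: bool


def pathway_protein_subgraph(interactome: nx.Graph, members) -> nx.Graph:
    """Induced interactome subgraph on the pathway members present in it.

    Members absent from the interactome are dropped with a warning; fewer
    than 2 present members is an error (listing the missing identifiers).
    """
    members = {str(m).upper() for m in members}
    present = sorted(members & set(interactome.nodes))
    missing = sorted(members - set(interactome.nodes))
    if missing:
        warnings.warn(f"{len(missing)} pathway members absent from interactome: {missing}")
    if len(present) < 2:
        raise DataError(
            f"fewer than 2 pathway members present in the interactome; missing: {missing}"
        )
    return interactome.subgraph(present).copy()


def protein_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Centrality triplets with dense ranks (1 = most central, ties share a rank)."""
    frame = node_centralities(graph).reset_index().rename(columns={"node": "protein_id"})
    for col in ("betweenness", "closeness", "degree"):
        frame[f"rank_{col}"] = frame[col].rank(method="dense", ascending=False).astype(int)
    frame["borda_score"] = (
        frame["rank_betweenness"] + frame["rank_closeness"] + frame["rank_degree"]
    )
    return frame.sort_values(
        ["borda_score", "betweenness", "protein_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def consensus_central_protein(triplets: pd.DataFrame, pathway_id: str = "") -> TargetCall:
    """The Borda-consensus most central protein among the triplets."""
    if not len(triplets):
        raise ParameterError("need at least one centrality triplet")
    frame = triplets.sort_values(
        ["borda_score", "betweenness", "protein_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    winner = frame.iloc[0]
    tied = bool(
        (
            (frame["borda_score"] == winner["borda_score"])
            & (frame["betweenness"] == winner["betweenness"])
        ).sum()
        > 1
    )
    return TargetCall(
        pathway_id=pathway_id,
        protein_id=str(winner["protein_id"]),
        borda_score=int(winner["borda_score"]),
        betweenness=float(winner["betweenness"]),
        closeness=float(winner["closeness"]),
        degree=float(winner["degree"]),
        tied=tied,
    )
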