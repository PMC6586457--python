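"""Degree and betweenness centrality on the main connected component.

Betweenness follows the standard shortest-path definition on unweighted
graphs: for a node v, the sum over unordered pairs s != t (both different
from v) of sigma_st(v) / sigma_st, where sigma_st counts shortest s-t paths
and sigma_st(v) those passing through v as an interior node.  Values are
normalised by 2 / ((n-1)(n-2)) so they lie in [0, 1]; for n <= 2 every value
is 0.  Edge confidences act only as an upstream filter, never as distances.

The per-node table is a :class:`pandas.DataFrame` indexed by node id with
columns ``degree``, ``betweenness``, ``degree_rank`` and ``betweenness_rank``
(competition ranking: 1 = highest, ties share the smaller rank).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .network_io import GeneNode, InteractionNetwork

CENTRALITY_METRICS = ("degree", "betweenness")

#: Per-node centrality table (DataFrame alias used in signatures).
CentralityTable = pd.DataFrame


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest component; size ties break towards the
    component containing the lexicographically smallest node id."""
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot take the largest component of an empty network")
    components = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    sub = net.subgraph(components[0]).copy()
    sub.graph["name"] = f"{net.graph.get('name', 'network')}_lcc"
    return sub


def count_isolated_nodes(net: InteractionNetwork) -> int:
    """Number of degree-0 nodes."""
    return sum(1 for n in net.nodes() if net.degree(n) == 0)


def compute_centrality(net: InteractionNetwork) -> CentralityTable:
    """Compute degree and normalised betweenness for a connected network.

    Raises
    ------
    ValidationError
        If the network is empty or disconnected (extract the main component
        first with :func:`largest_connected_component`).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValidationError("cannot compute centrality on an empty network")
    if n > 1 and not nx.is_connected(net):
        raise ValidationError(
            "network is disconnected; call largest_connected_component first"
        )
    bc = nx.betweenness_centrality(net, normalized=(n > 2))
    if n <= 2:  # normalisation factor undefined; all interior counts are 0
        bc = {v: 0.0 for v in net.nodes()}
    table = pd.DataFrame(
        {
            "degree": pd.Series({v: d for v, d in net.degree()}, dtype=int),
            "betweenness": pd.Series(bc, dtype=float),
        }
    )
    table.index.name = "id"
    table = table.sort_index()
    for metric in CENTRALITY_METRICS:
        table[f"{metric}_rank"] = (
            table[metric].rank(method="min", ascending=False).astype(int)
        )
    return table


def rank_nodes(table: CentralityTable, metric: str) -> list[str]:
    """Node ids sorted descending by *metric*; ties ascending by id."""
    if metric not in CENTRALITY_METRICS:
        raise ConfigurationError(
            f"unknown metric {metric!r}; expected one of {CENTRALITY_METRICS}"
        )
    if table.empty:
        raise ValidationError("centrality table is empty")
    return sorted(table.index, key=lambda v: (-table.at[v, metric], v))


def write_centrality_report(
    table: CentralityTable,
    path: str | Path,
    metadata: Mapping[str, GeneNode] | None = None,
) -> None:
    """Write the per-node report TSV (id, symbol, disease_score, degree,
    betweenness to 6 decimals, and both ranks), ordered by degree rank."""
    metadata = metadata or {}
    rows = []
    for v in rank_nodes(table, "degree"):
        meta = metadata.get(v)
        rows.append(
            {
                "id": v,
                "symbol": meta.symbol if meta else v,
                "disease_score": "" if meta is None or meta.disease_score is None
                else f"{meta.disease_score:g}",
                "degree": int(table.at[v, "degree"]),
                "betweenness": f"{table.at[v, 'betweenness']:.6f}",
                "degree_rank": int(table.at[v, "degree_rank"]),
                "betweenness_rank": int(table.at[v, "betweenness_rank"]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
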