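"""Hub / bottleneck selection, backbone extraction and super hub-bottlenecks.

A *hub* is a node in the top fraction (default 10%) of the degree
distribution of the analysed component; a *bottleneck* is a node in the top
fraction of betweenness centrality; their intersection gives the
*hub-bottlenecks*.  The *backbone* of a hub set is the subnetwork of the
hubs, their neighbours, and every edge incident to at least one hub — the
part of the network whose integrity the hubs carry.  Re-running the
centrality analysis inside the backbone and keeping the hub-bottlenecks that
stay in the top fraction by BOTH metrics yields the *super hub-bottlenecks*.

Selection sizes use ceiling rounding (a 148-node component at 10% gives 15
nodes) and the deterministic tie rule of :func:`hubnet.centrality.rank_nodes`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .centrality import (
    CentralityTable,
    compute_centrality,
    largest_connected_component,
    rank_nodes,
)
from .errors import ConfigurationError, ValidationError
from .network_io import InteractionNetwork


@dataclass(frozen=True)
class HubSelection:
    """Top-fraction hub and bottleneck lists and their intersection."""

    fraction: float
    hubs: tuple[str, ...]
    bottlenecks: tuple[str, ...]
    hub_bottlenecks: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "hub_bottlenecks", frozenset(self.hubs) & frozenset(self.bottlenecks)
        )


@dataclass(frozen=True)
class BackboneResult:
    """Hub-incident backbone and its comparison with the parent network."""

    backbone: InteractionNetwork
    node_similarity_pct: float
    edge_similarity_pct: float
    backbone_centrality: CentralityTable


def select_top_fraction(table: CentralityTable, metric: str, fraction: float) -> list[str]:
    """First ceil(fraction * n) nodes of the metric's ranking."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction {fraction} outside (0, 1]")
    ranked = rank_nodes(table, metric)
    # guard float noise: 0.1 * 150 must give 15, not 16
    k = math.ceil(fraction * len(ranked) - 1e-9)
    return ranked[:k]


def select_hubs_and_bottlenecks(
    table: CentralityTable,
    fraction: float = 0.10,
    bottleneck_count: int | None = None,
) -> HubSelection:
    """Select hubs and bottlenecks at the same top fraction.

    ``bottleneck_count`` optionally overrides the size of the bottleneck list
    only (the top-k by betweenness), for panels that pad the bottleneck side.
    """
    hubs = select_top_fraction(table, "degree", fraction)
    if bottleneck_count is None:
        bottlenecks = select_top_fraction(table, "betweenness", fraction)
    else:
        if bottleneck_count < 1:
            raise ConfigurationError("bottleneck_count must be >= 1")
        bottlenecks = rank_nodes(table, "betweenness")[:bottleneck_count]
    return HubSelection(fraction=fraction, hubs=tuple(hubs), bottlenecks=tuple(bottlenecks))


def hub_bottleneck_intersection(
    hubs: Iterable[str], bottlenecks: Iterable[str]
) -> frozenset[str]:
    """Nodes common to the hub and bottleneck lists (order-independent)."""
    return frozenset(hubs) & frozenset(bottlenecks)


def build_backbone(main: InteractionNetwork, hubs: Iterable[str]) -> BackboneResult:
    """Extract the hub-incident backbone and score its similarity to *main*.

    The backbone keeps the hubs, every neighbour of a hub, and every edge of
    *main* with at least one hub endpoint.  Node similarity is
    100 * |V_backbone| / |V_main| (the headline figure); edge similarity is
    the analogous edge-count ratio.  Centrality is recomputed on the
    backbone's largest connected component.
    """
    hub_set = frozenset(hubs)
    if not hub_set:
        raise ValidationError("hub set is empty")
    missing = hub_set - set(main.nodes())
    if missing:
        raise ValidationError(f"hubs not present in network: {sorted(missing)}")
    backbone = nx.Graph(name=f"{main.graph.get('name', 'network')}_backbone")
    backbone.add_nodes_from(hub_set)
    for a, b, data in main.edges(data=True):
        if a in hub_set or b in hub_set:
            backbone.add_edge(a, b, **data)
    node_sim = 100.0 * backbone.number_of_nodes() / main.number_of_nodes()
    edge_sim = (
        100.0 * backbone.number_of_edges() / main.number_of_edges()
        if main.number_of_edges()
        else 100.0
    )
    bc_table = compute_centrality(largest_connected_component(backbone))
    return BackboneResult(
        backbone=backbone,
        node_similarity_pct=node_sim,
        edge_similarity_pct=edge_sim,
        backbone_centrality=bc_table,
    )


def super_hub_bottlenecks(
    backbone_result: BackboneResult,
    hub_bottlenecks: Iterable[str],
    fraction: float = 0.10,
) -> frozenset[str]:
    """Hub-bottlenecks that stay in the backbone's top fraction by both
    degree and betweenness."""
    table = backbone_result.backbone_centrality
    top_deg = set(select_top_fraction(table, "degree", fraction))
    top_bet = set(select_top_fraction(table, "betweenness", fraction))
    return frozenset(hub_bottlenecks) & top_deg & top_bet


def write_selection_report(
    table: CentralityTable,
    selection: HubSelection,
    supers: frozenset[str],
    path: str | Path,
) -> None:
    """Per-node flag table: hub / bottleneck / hub-bottleneck / super."""
    rows = []
    for v in rank_nodes(table, "degree"):
        rows.append(
            {
                "id": v,
                "degree": int(table.at[v, "degree"]),
                "betweenness": f"{table.at[v, 'betweenness']:.6f}",
                "is_hub": v in selection.hubs,
                "is_bottleneck": v in selection.bottlenecks,
                "is_hub_bottleneck": v in selection.hub_bottlenecks,
                "is_super_hub_bottleneck": v in supers,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
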