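"""Typed action subnetworks over a selected gene panel.

An action map restricts a scored action list (activation / expression /
inhibition) to a gene panel and a score cutoff.  Edges are identified by
(unordered endpoint pair, mode) — action files list orientations
inconsistently, so direction is ignored for identity, while several modes on
the same pair remain distinct edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import ConfigurationError, ValidationError
from .network_io import ActionEdge

SIMILARITY_METHODS = ("jaccard", "containment")

MODE_COLORS = {"activation": "green", "expression": "blue", "inhibition": "red"}


@dataclass(frozen=True)
class ActionNetwork:
    """Typed relations retained within a gene panel at a score cutoff."""

    genes: frozenset[str]
    edges: tuple[ActionEdge, ...]
    score_cutoff: float

    def edge_keys(self) -> frozenset[tuple[tuple[str, str], str]]:
        """Identity set used for comparison: {(sorted pair, mode)}."""
        return frozenset((e.pair, e.mode) for e in self.edges)


def build_action_network(
    actions: Iterable[ActionEdge],
    genes: Iterable[str],
    score_cutoff: float = 0.5,
) -> ActionNetwork:
    """Keep actions whose endpoints both lie in *genes* and whose score
    reaches the cutoff; duplicate (pair, mode) entries collapse to the
    highest-scoring record."""
    if not 0.0 <= score_cutoff <= 1.0:
        raise ConfigurationError(f"score_cutoff {score_cutoff} outside [0, 1]")
    panel = frozenset(g.upper() for g in genes)
    if not panel:
        raise ValidationError("gene panel is empty")
    best: dict[tuple[tuple[str, str], str], ActionEdge] = {}
    for e in actions:
        if e.source not in panel or e.target not in panel or e.score < score_cutoff:
            continue
        key = (e.pair, e.mode)
        if key not in best or e.score > best[key].score:
            best[key] = e
    edges = tuple(sorted(best.values(), key=lambda e: (e.pair, e.mode)))
    return ActionNetwork(genes=panel, edges=edges, score_cutoff=score_cutoff)


def isolated_members(net: ActionNetwork) -> frozenset[str]:
    """Panel genes with no retained action edge."""
    touched = {g for e in net.edges for g in (e.source, e.target)}
    return net.genes - touched


def action_map_similarity(a: ActionNetwork, b: ActionNetwork, method: str = "jaccard") -> float:
    """Percentage similarity of two action maps on (pair, mode) edge identity.

    ``jaccard`` is 100 * |intersection| / |union|; ``containment`` is
    100 * |intersection| / min(|E_a|, |E_b|) — the coverage of the smaller
    map by the larger.  Two empty maps are 100% similar under both.
    """
    if method not in SIMILARITY_METHODS:
        raise ConfigurationError(f"unknown similarity method {method!r}")
    ka, kb = a.edge_keys(), b.edge_keys()
    if not ka and not kb:
        return 100.0
    inter = len(ka & kb)
    if method == "jaccard":
        return 100.0 * inter / len(ka | kb)
    denom = min(len(ka), len(kb))
    return 100.0 * inter / denom if denom else 0.0


def write_action_network(net: ActionNetwork, path: str | Path, dialect: str = "tsv") -> None:
    """Export an action map as TSV (source, target, mode, score) or GraphML
    with mode and the conventional colour as edge attributes."""
    path = Path(path)
    if dialect == "tsv":
        with path.open("w") as fh:
            fh.write("source\ttarget\tmode\tscore\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.mode}\t{e.score:.6f}\n")
    elif dialect == "graphml":
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(net.genes))
        for e in net.edges:
            g.add_edge(
                e.source,
                e.target,
                mode=e.mode,
                score=e.score,
                color=MODE_COLORS[e.mode],
                directed=e.directed,
            )
        nx.write_graphml(g, path)
    else:
        raise ConfigurationError(f"unknown action export dialect {dialect!r}")
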