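"""End-to-end orchestration: ingest → component → centrality → selection →
backbone → actions → enrichment, with a run manifest for reproducibility.

Each stage writes its table under the configured output directory; the
manifest records the effective configuration, input checksums and per-stage
sizes, so an identical re-run reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .action_map import (
    ActionNetwork,
    action_map_similarity,
    build_action_network,
    isolated_members,
    write_action_network,
)
from .centrality import (
    compute_centrality,
    count_isolated_nodes,
    largest_connected_component,
    write_centrality_report,
)
from .enrichment import (
    EnrichmentConfig,
    group_terms,
    run_enrichment,
    write_enrichment_report,
)
from .errors import HubnetError
from .hub_analysis import (
    build_backbone,
    select_hubs_and_bottlenecks,
    super_hub_bottlenecks,
    write_selection_report,
)
from .network_io import (
    read_actions,
    read_gene_sets,
    read_interactions,
    read_node_metadata,
    write_network,
)

logger = logging.getLogger(__name__)

STAGES = (
    "ingest",
    "component",
    "centrality",
    "selection",
    "backbone",
    "actions",
    "enrichment",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and bookkeeping for one pipeline run.

    The defaults are the standard settings of the analysis: confidence and
    action cutoffs of 0.5, top-10% hub/bottleneck selection, and the usual
    enrichment filters (alpha 0.05, >= 3 genes per term, >= 4% of the term,
    ontology levels 2-8, kappa 0.5).
    """

    interaction_score_cutoff: float = 0.5
    interaction_dialect: str = "string_tsv"
    geneset_dialect: str = "tsv_with_depth"
    hub_fraction: float = 0.10
    bottleneck_count: int | None = None
    action_score_cutoff: float = 0.5
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    seed: int = 0
    output_dir: str = "hubnet_out"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        enrich = raw.pop("enrichment", {})
        if isinstance(enrich, dict):
            enrich = EnrichmentConfig(**enrich)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise HubnetError(f"unknown config keys: {sorted(unknown)}")
        return cls(enrichment=enrich, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, inputs: dict[str, str]) -> dict[str, Any]:
    """Run every stage on an input bundle and return the manifest.

    ``inputs`` maps ``interactions`` (required) and optionally ``actions``,
    ``annotations``, ``metadata`` and ``universe`` to file paths.  Any stage
    failure raises with the stage name prefixed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "stages": [],
    }
    stage = "ingest"
    try:
        net = read_interactions(
            inputs["interactions"],
            dialect=config.interaction_dialect,
            score_cutoff=config.interaction_score_cutoff,
        )
        metadata = (
            read_node_metadata(inputs["metadata"]) if inputs.get("metadata") else {}
        )
        # the metadata file carries the full queried gene panel; genes with no
        # surviving interaction enter the network as isolated nodes
        net.add_nodes_from(g for g in metadata if g not in net)
        _log_stage(manifest, stage, nodes=net.number_of_nodes(), edges=net.number_of_edges())

        stage = "component"
        component = largest_connected_component(net)
        n_isolated = count_isolated_nodes(net)
        write_network(component, out / "component.tsv", dialect="plain_tsv")
        _log_stage(
            manifest, stage,
            nodes=component.number_of_nodes(),
            edges=component.number_of_edges(),
            isolated_in_full_network=n_isolated,
        )

        stage = "centrality"
        table = compute_centrality(component)
        write_centrality_report(table, out / "centrality.tsv", metadata)
        _log_stage(manifest, stage, nodes=len(table))

        stage = "selection"
        selection = select_hubs_and_bottlenecks(
            table, fraction=config.hub_fraction, bottleneck_count=config.bottleneck_count
        )
        _log_stage(
            manifest, stage,
            hubs=len(selection.hubs),
            bottlenecks=len(selection.bottlenecks),
            hub_bottlenecks=len(selection.hub_bottlenecks),
        )

        stage = "backbone"
        backbone = build_backbone(component, selection.hubs)
        supers = super_hub_bottlenecks(
            backbone, selection.hub_bottlenecks, config.hub_fraction
        )
        write_network(backbone.backbone, out / "backbone.graphml", dialect="graphml")
        write_selection_report(table, selection, supers, out / "selection.tsv")
        _log_stage(
            manifest, stage,
            nodes=backbone.backbone.number_of_nodes(),
            edges=backbone.backbone.number_of_edges(),
            node_similarity_pct=round(backbone.node_similarity_pct, 2),
            edge_similarity_pct=round(backbone.edge_similarity_pct, 2),
            super_hub_bottlenecks=sorted(supers),
        )

        stage = "actions"
        action_info: dict[str, Any] = {}
        if inputs.get("actions"):
            all_actions = read_actions(inputs["actions"], score_cutoff=0.0)
            hub_map = build_action_network(
                all_actions, selection.hubs, config.action_score_cutoff
            )
            combined_panel = set(selection.hubs) | set(selection.bottlenecks)
            combined_map = build_action_network(
                all_actions, combined_panel, config.action_score_cutoff
            )
            write_action_network(hub_map, out / "actions_hubs.tsv")
            write_action_network(combined_map, out / "actions_hub_bottlenecks.tsv")
            write_action_network(
                combined_map, out / "actions_hub_bottlenecks.graphml", dialect="graphml"
            )
            action_info = {
                "hub_map_edges": len(hub_map.edges),
                "combined_map_edges": len(combined_map.edges),
                "similarity_pct": round(action_map_similarity(hub_map, combined_map), 2),
                "isolated_in_combined_map": sorted(isolated_members(combined_map)),
            }
        _log_stage(manifest, stage, **(action_info or {"skipped": True}))

        stage = "enrichment"
        enrich_info: dict[str, Any] = {}
        if inputs.get("annotations"):
            annotation = read_gene_sets(
                inputs["annotations"], dialect=config.geneset_dialect
            )
            if inputs.get("universe"):
                universe = {
                    line.strip().upper()
                    for line in Path(inputs["universe"]).read_text().splitlines()
                    if line.strip()
                }
            else:  # default universe: all annotated genes
                universe = set().union(*(t.genes for t in annotation))
            results = run_enrichment(
                selection.hubs, annotation, universe, config.enrichment
            )
            groups = group_terms(results, config.enrichment.kappa_threshold)
            write_enrichment_report(results, groups, out / "enrichment.tsv")
            enrich_info = {
                "terms_tested": len(results),
                "terms_passing": sum(r.passes_filters for r in results),
                "groups": len(groups),
                "top_group_leading_term": groups[0].leading_term if groups else None,
            }
        _log_stage(manifest, stage, **(enrich_info or {"skipped": True}))
    except HubnetError as exc:
        raise HubnetError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _log_stage(manifest: dict[str, Any], name: str, **info: Any) -> None:
    logger.info("stage %s: %s", name, info)
    manifest["stages"].append({"stage": name, **info})
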