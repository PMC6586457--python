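"""Seeded synthetic inputs with the structure the analysis assumes.

The generator emulates the scale of a disease-query interaction network: a
preferential-attachment (heavy-tailed) connected core of 175 genes with
~1,150 edges, plus 75 isolated genes, for 250 nodes in total.  A small set of
planted hubs receives extra random attachments so that they dominate both
degree and betweenness and can be recovered by the selection stage.  Action
files draw a mode and a Beta-distributed score per interaction, optionally
withholding above-cutoff actions from designated genes to plant isolated
panel members.  Annotation files mix decoy terms, whose overlap with a query
panel is hypergeometric by construction, with planted terms seeded with a
fixed number of query genes.

Everything is driven by one integer seed per generator call, so identical
specs reproduce byte-identical files.  The module also carries two kinds of
fixed fixtures: the published 15-row hub table of the anorexia-nervosa
interactome study (degree, betweenness, disease scores and hub-bottleneck
marks) and a deterministic three-shell "structured component" whose backbone
arithmetic mirrors that study's printed 148-node / 109-node figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import CentralityTable, compute_centrality, largest_connected_component
from .errors import ValidationError
from .hub_analysis import select_top_fraction
from .network_io import (
    ActionEdge,
    GeneNode,
    GeneSet,
    InteractionNetwork,
    write_actions,
    write_gene_sets,
    write_network,
    write_node_metadata,
)

_MODES = ("activation", "expression", "inhibition")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic input bundle.

    Defaults reproduce the published study's scale: 250 genes of which 75 are
    isolated, a connected core whose edge count lands near 1,170
    (attachment_edges=6 on 175 nodes gives ~1,014 attachment edges, plus
    6 planted hubs x 25 boost edges), and six planted hubs wired to dominate
    both centrality metrics.
    """

    seed: int = 0
    n_nodes: int = 250
    n_isolated: int = 75
    attachment_edges: int = 6
    n_planted_hubs: int = 6
    planted_hub_boost: int = 25
    action_mode_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    score_beta: tuple[float, float] = (5.0, 2.0)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    n_planted_terms: int = 1
    planted_overlap: int = 5

    def __post_init__(self) -> None:
        if self.n_isolated >= self.n_nodes:
            raise ValidationError("n_isolated must be < n_nodes")
        if abs(sum(self.action_mode_probs) - 1.0) > 1e-9:
            raise ValidationError("action_mode_probs must sum to 1")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi <= self.n_nodes:
            raise ValidationError("term_size_range must lie within [1, n_nodes]")
        if self.n_planted_terms > self.n_terms:
            raise ValidationError("n_planted_terms must be <= n_terms")

    @property
    def planted_hub_ids(self) -> tuple[str, ...]:
        return tuple(f"HUB{i + 1:02d}" for i in range(self.n_planted_hubs))


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent substream per generator so e.g. action draws do not shift
    # the network topology
    return np.random.default_rng([spec.seed, stream])


def generate_ppi(spec: SyntheticSpec) -> InteractionNetwork:
    """Preferential-attachment core + planted hubs + isolated nodes.

    Planted hubs occupy the earliest attachment positions (already
    heavy-tailed) and receive ``planted_hub_boost`` extra uniform-random
    attachments each, which reliably puts them at the top of both the degree
    and the betweenness rankings.  Edge confidences are Beta draws.
    """
    n_core = spec.n_nodes - spec.n_isolated
    if spec.attachment_edges >= n_core:
        raise ValidationError(
            f"attachment_edges ({spec.attachment_edges}) must be < connected "
            f"node count ({n_core})"
        )
    rng = _rng(spec, 1)
    g = nx.barabasi_albert_graph(
        n_core, spec.attachment_edges, seed=int(rng.integers(2**31))
    )
    for h in range(spec.n_planted_hubs):
        candidates = sorted(set(range(n_core)) - {h} - set(g.neighbors(h)))
        n_extra = min(spec.planted_hub_boost, len(candidates))
        for idx in rng.choice(len(candidates), size=n_extra, replace=False):
            g.add_edge(h, candidates[int(idx)])
    width = len(str(spec.n_nodes))
    mapping = {
        i: (f"HUB{i + 1:02d}" if i < spec.n_planted_hubs else f"G{i:0{width}d}")
        for i in range(n_core)
    }
    g = nx.relabel_nodes(g, mapping)
    a, b = spec.score_beta
    for u, v in sorted(g.edges(), key=lambda e: tuple(sorted(e))):
        g[u][v]["confidence"] = float(rng.beta(a, b))
    g.add_nodes_from(f"ISO{i:0{width}d}" for i in range(spec.n_isolated))
    g.graph["name"] = f"synthetic_seed{spec.seed}"
    return g


def generate_actions(
    net: InteractionNetwork,
    spec: SyntheticSpec,
    withhold: tuple[str, ...] = (),
    withhold_below: float = 0.5,
) -> list[ActionEdge]:
    """One typed, scored action per interaction edge.

    Edges touching a *withhold* gene get scores drawn uniformly below
    ``withhold_below``, so those genes end up isolated in any action map
    thresholded at that cutoff.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    rng = _rng(spec, 2)
    a, b = spec.score_beta
    held = frozenset(withhold)
    edges: list[ActionEdge] = []
    for u, v in sorted(net.edges(), key=lambda e: tuple(sorted(e))):
        mode = _MODES[int(rng.choice(3, p=list(spec.action_mode_probs)))]
        if u in held or v in held:
            score = float(rng.uniform(0.0, withhold_below))
        else:
            score = float(rng.beta(a, b))
        src, tgt = (u, v) if rng.random() < 0.5 else (v, u)
        edges.append(
            ActionEdge(source=src, target=tgt, mode=mode, score=score,
                       directed=bool(rng.random() < 0.5))
        )
    return edges


def generate_annotations(
    genes: frozenset[str] | set[str],
    spec: SyntheticSpec,
    query: frozenset[str] | set[str],
) -> list[GeneSet]:
    """Decoy terms with hypergeometric-null query overlap plus planted terms.

    Decoys sample their genes uniformly without replacement from *genes*;
    planted terms contain exactly ``planted_overlap`` query genes plus
    uniform non-query fill, so their overlap far exceeds the null
    expectation.  Term depths are uniform on [1, 10].
    """
    pool = sorted(g.upper() for g in genes)
    q = sorted(g.upper() for g in query)
    if not set(q) <= set(pool):
        raise ValidationError("query must be a subset of the gene pool")
    if spec.planted_overlap > len(q):
        raise ValidationError("planted_overlap exceeds the query size")
    rng = _rng(spec, 3)
    lo, hi = spec.term_size_range
    non_query = sorted(set(pool) - set(q))
    terms: list[GeneSet] = []
    for i in range(spec.n_planted_terms):
        size = max(int(rng.integers(lo, hi + 1)), spec.planted_overlap)
        picked = [q[int(j)] for j in rng.choice(len(q), spec.planted_overlap, replace=False)]
        n_fill = min(size - spec.planted_overlap, len(non_query))
        picked += [non_query[int(j)] for j in rng.choice(len(non_query), n_fill, replace=False)]
        terms.append(
            GeneSet(
                term_id=f"PLANTED{i + 1}",
                term_name=f"planted enriched term {i + 1}",
                genes=frozenset(picked),
                namespace="BP",
                depth=int(rng.integers(1, 11)),
            )
        )
    for i in range(spec.n_terms - spec.n_planted_terms):
        size = int(rng.integers(lo, hi + 1))
        picked = [pool[int(j)] for j in rng.choice(len(pool), size, replace=False)]
        terms.append(
            GeneSet(
                term_id=f"T{i + 1:04d}",
                term_name=f"decoy term {i + 1}",
                genes=frozenset(picked),
                namespace="BP" if i % 2 == 0 else "MF",
                depth=int(rng.integers(1, 11)),
            )
        )
    return terms


# --------------------------------------------------------------------------
# Fixed fixtures

# Published 15-row hub table of the anorexia-nervosa interactome study:
# (symbol, description, disease score, degree, normalised betweenness,
#  hub-bottleneck mark).
_TABLE1_ROWS = [
    ("LEP", "Leptin", 3.0, 69, 0.13, True),
    ("INS", "Insulin", 2.02, 68, 0.12, True),
    ("POMC", "Proopiomelanocortin", 2.22, 65, 0.07, True),
    ("NPY", "Neuropeptide Y", 2.34, 58, 0.03, False),
    ("GCG", "Glucagon", 1.0, 54, 0.05, True),
    ("SST", "Somatostatin", 1.41, 51, 0.04, True),
    ("NPS", "Neuropeptide S", 2.03, 49, 0.02, False),
    ("CRH", "Corticotropin releasing hormone", 2.25, 48, 0.04, False),
    ("ALB", "Albumin", 1.35, 45, 0.10, True),
    ("CCK", "Cholecystokinin", 1.93, 40, 0.007, False),
    ("TRH", "Thyrotropin-releasing hormone", 1.60, 40, 0.009, False),
    ("IL6", "Interleukin 6 (interferon, beta 2)", 0.8, 39, 0.04, False),
    ("IGF1", "Insulin-like growth factor 1 (somatomedin C)", 2.60, 38, 0.02, False),
    ("OXT", "Oxytocin/neurophysin I prepropeptide", 1.92, 38, 0.01, False),
    ("GAL", "Galanin/GMAP prepropeptide", 1.34, 38, 0.01, False),
]

# Published table of the four bottlenecks left isolated in the combined
# hub+bottleneck action map: (symbol, betweenness, BC rank, degree, degree rank).
_TABLE2_ROWS = [
    ("NR3C1", 0.06, 5, 12, 69),
    ("NPL", 0.04, 10, 3, 105),
    ("TNF", 0.04, 12, 18, 52),
    ("HNRNPU", 0.03, 14, 4, 103),
]


def fixture_table1() -> tuple[CentralityTable, dict[str, GeneNode], frozenset[str]]:
    """The published hub table: centrality values, metadata, and the
    hub-bottleneck marker set."""
    table = pd.DataFrame(
        {
            "degree": [r[3] for r in _TABLE1_ROWS],
            "betweenness": [r[4] for r in _TABLE1_ROWS],
        },
        index=pd.Index([r[0] for r in _TABLE1_ROWS], name="id"),
    )
    for metric in ("degree", "betweenness"):
        table[f"{metric}_rank"] = (
            table[metric].rank(method="min", ascending=False).astype(int)
        )
    metadata = {
        sym: GeneNode(id=sym, symbol=sym, description=desc, disease_score=ds)
        for sym, desc, ds, _deg, _bc, _mark in _TABLE1_ROWS
    }
    marked = frozenset(sym for sym, *_rest, mark in _TABLE1_ROWS if mark)
    return table, metadata, marked


def fixture_table2() -> pd.DataFrame:
    """The published isolated-bottleneck table (betweenness/degree + ranks)."""
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=["id", "betweenness", "betweenness_rank", "degree", "degree_rank"],
    ).set_index("id")


def structured_component(
    n_nodes: int = 148, n_hubs: int = 15, n_inner: int = 94
) -> tuple[InteractionNetwork, list[str]]:
    """Deterministic three-shell network for backbone arithmetic demos.

    A clique of ``n_hubs`` hubs, an inner shell of ``n_inner`` nodes each
    attached to one hub, and an outer shell (the remainder) attached only to
    inner nodes.  The hubs are exactly the top ``n_hubs`` nodes by degree,
    and the hub backbone covers hubs + inner shell, so with the defaults the
    node-overlap similarity is 100 * 109 / 148 ~ 74%.

    Returns the network and the hub id list.
    """
    n_outer = n_nodes - n_hubs - n_inner
    if n_outer < 0 or n_hubs < 2 or n_inner < n_hubs:
        raise ValidationError("infeasible shell sizes")
    g = nx.Graph(name="structured_component")
    hubs = [f"HUB{i + 1:02d}" for i in range(n_hubs)]
    inner = [f"P{i + 1:03d}" for i in range(n_inner)]
    outer = [f"Q{i + 1:03d}" for i in range(n_outer)]
    for i, a in enumerate(hubs):
        for b in hubs[i + 1 :]:
            g.add_edge(a, b, confidence=0.9)
    for j, p in enumerate(inner):
        g.add_edge(p, hubs[j % n_hubs], confidence=0.8)
    for j, qnode in enumerate(outer):
        first = inner[j % n_inner]
        second = inner[(j * 7 + 3) % n_inner]
        if second == first:
            second = inner[(j * 7 + 4) % n_inner]
        g.add_edge(qnode, first, confidence=0.7)
        g.add_edge(qnode, second, confidence=0.7)
    return g, hubs


def write_bundle(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, str]:
    """Generate and write a complete input bundle + manifest.

    The annotation query panel is the top-10% degree list of the generated
    network's main component after the standard 0.5 confidence filter — the
    same panel the pipeline will select at its default settings — so planted
    terms are recoverable end-to-end.  Returns the file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = generate_ppi(spec)
    filtered = nx.Graph(name=net.graph["name"])
    filtered.add_nodes_from(net.nodes())
    filtered.add_edges_from(
        (u, v, d) for u, v, d in net.edges(data=True) if d["confidence"] >= 0.5
    )
    component = largest_connected_component(filtered)
    hubs = select_top_fraction(compute_centrality(component), "degree", 0.10)
    actions = generate_actions(net, spec)
    annotations = generate_annotations(set(net.nodes()), spec, frozenset(hubs))
    rng = _rng(spec, 4)
    metadata = {
        n: GeneNode(id=n, symbol=n, description="synthetic gene",
                    disease_score=round(float(rng.uniform(0, 3)), 2))
        for n in sorted(net.nodes())
    }
    files = {
        "interactions": str(out / "interactions.tsv"),
        "actions": str(out / "actions.tsv"),
        "annotations": str(out / "annotations.tsv"),
        "metadata": str(out / "metadata.tsv"),
    }
    write_network(net, files["interactions"], dialect="string_tsv")
    write_actions(actions, files["actions"])
    write_gene_sets(annotations, files["annotations"], dialect="tsv_with_depth")
    write_node_metadata(metadata, files["metadata"])
    manifest = {"spec": asdict(spec), "files": files}
    (out / "bundle_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return files
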