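# Methods

## Scope and model

hubnet analyses an undirected simple graph of gene nodes whose edges carry an
interaction-confidence score in [0, 1]. Confidence acts purely as an ingest
filter (default cutoff 0.5, inclusive); all path-based quantities use
unweighted hop distances, matching the topology-only convention of the
Cytoscape Network Analyzer workflow this pipeline reproduces. Files whose
scores exceed 1 are taken to be on the STRING 0–1000 integer scale and
divided by 1000; any score above 1000 or below 0 is a parse error rather
than a silent clamp. Self-loops are dropped (with a warning) and duplicate
unordered pairs collapse to the maximum confidence, because the betweenness
definition below assumes a simple graph. Gene identifiers are uppercased on
ingest so mixed symbol stylings compare equal.

## Centrality

Degree is the incident-edge count within the analysed component. Betweenness
is the interior-node shortest-path fraction, normalised by `2/((n−1)(n−2))`
so a star centre scores exactly 1; endpoints do not count as on-path, and
graphs with `n ≤ 2` score 0 everywhere. The normalised form was chosen
because published hub tables report BC values like 0.13 that only make sense
on the [0, 1] scale. Computation delegates to the Brandes algorithm
(networkx); the test suite checks it against an exhaustive shortest-path
enumeration oracle on hundreds of small random graphs (≤ 12 nodes, 1e-9)
plus closed forms (star, complete graph, path, 4-cycle).

Rankings are deterministic: descending by metric, ties ascending by gene id,
with competition ranks (ties share the smaller rank). The tie rule is a
reproducibility device, not a scientific claim.

## Hub selection and the backbone

Hubs (bottlenecks) are the top `⌈fraction·n⌉` nodes by degree (betweenness),
with `fraction = 0.10` by default — the ceiling reproduces the standard
148-node → 15-hub arithmetic. The ceiling computation subtracts 1e-9 before
rounding up so that float noise (e.g. `0.1·150 = 15.000000000000002`) cannot
inflate the selection by one. The bottleneck list size can be overridden
independently (`bottleneck_count`) for panel designs that pad the
bottleneck side; the hub-bottleneck set is always the plain intersection.

The backbone of a hub set is the *hub-incident* subgraph — hubs, all their
neighbours, and every edge with at least one hub endpoint — not the
hub-induced subgraph; the incident definition is what makes a 15-hub
backbone cover 109 of 148 nodes (≈ 74% node overlap). Node-overlap
percentage is the headline similarity figure; edge overlap is reported
alongside. Super hub-bottlenecks are the hub-bottlenecks that stay in the
top fraction by both metrics when centrality is recomputed on the backbone's
largest component; "both metrics" is this package's concrete rule for the
otherwise underspecified notion of the backbone's "most central" genes.

On preferential-attachment graphs the top-decile hubs neighbour nearly every
node, so the backbone covers most of the component and naturally central
genes can join the planted ones in the super set; recovery tests therefore
assert containment of the planted ids (or use a top-k fraction sized to the
planted count) rather than set equality.

## Action maps

An action map restricts a scored, typed relation list (activation /
expression / inhibition; other modes are skipped with a logged count) to a
gene panel and a score cutoff (default 0.5, inclusive). Edge identity is the
unordered gene pair plus the mode: direction is ignored for identity because
action exports list orientations inconsistently, while distinct modes on one
pair remain distinct edges. Map similarity is the Jaccard percentage over
these identities (two empty maps count as 100% similar); a containment
variant (`|∩| / min(|A|, |B|)`) is available since published "percent
similar" figures rarely state their denominator.

## Enrichment

Each term is tested against `Hypergeom(N, K, n)` with all counts restricted
to the declared universe; the two-sided p-value doubles the smaller tail,
capped at 1, with near-equal tails (relative 1e-9) classified as enrichment.
Doubling is the standard two-sided rule; tail probabilities come from
scipy's stable implementation and are verified against exact rational
arithmetic for every admissible configuration with N ≤ 12 (1e-12). The
universe is an explicit input (defaulting to all annotated genes) because
enrichment conclusions are meaningless without stating it; query genes
outside it are dropped with a logged count.

Correction is the Bonferroni step-down (Holm) procedure across all tested
terms (statsmodels), verified against the textbook definition. Filters
follow the conventional ClueGO-style defaults: ≥ 3 query genes per term,
≥ 4% of the term's genes recovered (`100·k/K`), corrected p < 0.05, and an
ontology-level window of 2–8 applied only when a term carries a depth —
terms without depth are never level-filtered.

Passing terms are linked when the Cohen kappa of their membership vectors —
computed over the union of the passing terms' genes, mirroring the
term-to-term comparison context — reaches the threshold (default 0.5), and
groups are the connected components of that graph, each led by its
lowest-corrected-p member (ties by term id). Connected components are a
deliberate simplification of iterative group merging; the behaviour is
isolated behind `group_terms` so a different grouping policy can be swapped
in.

## Synthetic data

`SyntheticSpec` defaults encode the disease-interactome scale the pipeline
is meant to exercise: 250 genes with 75 isolated; a Barabási–Albert core on
the remaining 175 with 6 attachments per node (~1,014 edges) plus 6 planted
hubs with 25 extra uniform attachments each (~150 edges), landing near the
1,170-edge scale; Beta(5, 2) interaction confidences (mean ≈ 0.71, so the
0.5 filter removes a realistic minority); one action per edge with mode
probabilities (0.5, 0.25, 0.25) and the same Beta score law; and 50
annotation terms of 10–40 genes over the gene pool, one of them planted with
5 query genes. Preferential attachment was chosen over duplication-divergence
as a short, well-understood heavy-tail generator: only the scale and the
hub structure need emulating, not biological topology. Planted hubs occupy
the earliest attachment positions, so the boost compounds an already
heavy-tailed degree; this makes them dominate both degree and betweenness in
essentially every seed.

What the generator does *not* emulate: true PPI clustering/modularity,
confidence–topology correlation, ontology DAG structure (term depths are
independent uniform integers on [1, 10]), and correlated annotation between
related terms. Passing tests therefore demonstrate the correctness of the
selection, backbone, action and enrichment machinery under a controlled
null, not biological validity on real interactomes.

A planted overlap of 5 of 15 query genes in a ~25-gene term within a
500-gene universe makes the planted term rank first by corrected p but sit
near the 0.05 boundary after Holm — deliberately marginal. Demonstrations
that need a clearly passing group (the end-to-end recovery test, the README
example) raise the overlap to 8 explicitly.

The module also ships fixed fixtures: the published 15-row hub table of an
anorexia-nervosa interactome (degrees 69…38, BC 0.13…0.007, disease scores,
and the six marked hub-bottlenecks LEP, INS, POMC, GCG, SST, ALB), the
four-row isolated-bottleneck table, and a deterministic three-shell
"structured component" (15-hub clique, 94-node inner shell, 39-node outer
shell) whose top-decile selection yields exactly 15 hubs and whose backbone
covers 109 of 148 nodes — reproducing the published selection and similarity
arithmetic from first principles.

## Pipeline and numerical choices

The pipeline runs ingest → component → centrality → selection → backbone →
actions → enrichment, writing each table plus a manifest (config, input
SHA-256 checksums, per-stage sizes); re-running with the same inputs and
configuration is byte-identical. When a metadata file is supplied it is
treated as the full queried gene panel: genes without surviving interactions
enter the network as isolated nodes, so the isolated count refers to the
query, not just the edge list. Ties everywhere break lexicographically;
component ties break toward the component containing the smallest gene id;
degenerate inputs (empty network, empty hub set, empty universe, empty
query after restriction) raise validation errors naming the failing stage.

Test problem sizes were chosen to keep the full suite fast while remaining
informative: oracle sweeps use ≤ 12-node graphs (200 of them), the planted
recovery study uses 20 study-scale seeds, and the null false-positive study
uses 200 seeds of 50 terms each.

## Known limitations

- Edge-list dialects (plain/STRING TSV) cannot carry isolated nodes through
  a round trip; SIF (lone-node lines) and GraphML can.
- GMT files carry no namespace; namespaces are only populated when the
  caller sets them (the generator does) and default to "other".
- Betweenness ignores edge weights by design; there is no weighted-path or
  closeness/eigenvector variant.
- Kappa grouping is single-pass connected components, not ClueGO's
  iterative leading-term merging, so groups can be coarser than ClueGO's on
  dense term graphs.
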