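"""Readers and writers for the interaction-network dialects the pipeline touches.

Interaction networks are held as :class:`networkx.Graph` objects: undirected
simple graphs whose edges carry a ``confidence`` attribute in [0, 1].  The
supported on-disk dialects are the STRING protein-links table (two identifiers
plus a combined score, whitespace separated, scores usually on the 0-1000
integer scale), a plain three-column TSV, SIF (``A interacts B``; lone-node
lines keep isolated nodes), GraphML, the STRING actions table
(``item_a  item_b  mode  score  directed``) and GMT gene-set files.

Scores are auto-normalised: if any score in a file exceeds 1 the whole file is
taken to be on the 0-1000 integer scale and divided by 1000.  The confidence
cutoff (default 0.5, inclusive) is applied after normalisation.  Self-loops
are dropped with a warning; duplicate unordered pairs collapse to the maximum
confidence.  Gene identifiers are uppercased everywhere so that mixed symbol
stylings compare equal.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Alias used throughout the package for the network container.
InteractionNetwork = nx.Graph

ACTION_MODES = frozenset({"activation", "expression", "inhibition"})

INTERACTION_DIALECTS = ("string_tsv", "plain_tsv", "sif", "graphml")
GENESET_DIALECTS = ("gmt", "tsv_with_depth")


@dataclass(frozen=True)
class GeneNode:
    """Per-gene metadata: display symbol, free-text description and the
    disease-association score attached by a disease-centred database query."""

    id: str
    symbol: str = ""
    description: str = ""
    disease_score: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("gene id must be non-empty")
        if self.disease_score is not None and self.disease_score < 0:
            raise ValidationError(
                f"disease_score must be >= 0, got {self.disease_score} for {self.id}"
            )


@dataclass(frozen=True)
class ActionEdge:
    """A typed, scored relation (activation / expression / inhibition)."""

    source: str
    target: str
    mode: str
    score: float
    directed: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ACTION_MODES:
            raise ValidationError(f"unknown action mode {self.mode!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"action score {self.score} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair (canonical sorted order)."""
        return tuple(sorted((self.source, self.target)))  # type: ignore[return-value]


@dataclass(frozen=True)
class GeneSet:
    """An annotation term with its gene membership.

    ``depth`` is the term's level in the ontology hierarchy when known; terms
    read from plain GMT files have no depth and are never level-filtered.
    """

    term_id: str
    term_name: str
    genes: frozenset[str]
    namespace: str = "other"
    depth: int | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id} is empty")
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"depth must be >= 0 for {self.term_id}")


def _normalise_scores(raw: Sequence[float], path: str) -> list[float]:
    """Map a file's scores onto [0, 1], dividing by 1000 when any exceeds 1."""
    if any(s < 0 or s > 1000 for s in raw):
        bad = next(s for s in raw if s < 0 or s > 1000)
        raise ParseError(f"{path}: score {bad} outside both the 0-1 and 0-1000 scales")
    if any(s > 1 for s in raw):
        return [s / 1000.0 for s in raw]
    return list(raw)


def _parse_edge_lines(
    lines: Iterable[str], path: str, sep: str | None
) -> tuple[list[tuple[str, str]], list[float]]:
    pairs: list[tuple[str, str]] = []
    scores: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(sep)
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        a, b, raw_score = fields[0], fields[1], fields[2]
        try:
            score = float(raw_score)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric score {raw_score!r}") from None
        pairs.append((a.upper(), b.upper()))
        scores.append(score)
    return pairs, scores


def _parse_sif(lines: Iterable[str], path: str) -> tuple[list[tuple[str, str]], list[str]]:
    """SIF: ``node relation target [target ...]``; a lone field is an isolated node."""
    pairs: list[tuple[str, str]] = []
    singletons: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            singletons.append(fields[0].upper())
        elif len(fields) == 2:
            raise ParseError(f"{path}:{lineno}: SIF line has a relation but no target")
        else:
            src = fields[0].upper()
            for tgt in fields[2:]:
                pairs.append((src, tgt.upper()))
    return pairs, singletons


def _build_network(
    pairs: Sequence[tuple[str, str]],
    confidences: Sequence[float],
    score_cutoff: float,
    name: str,
    extra_nodes: Iterable[str] = (),
) -> InteractionNetwork:
    net = nx.Graph(name=name)
    n_loops = 0
    for (a, b), conf in zip(pairs, confidences):
        if a == b:
            n_loops += 1
            continue
        if conf < score_cutoff:
            continue
        if net.has_edge(a, b):
            net[a][b]["confidence"] = max(net[a][b]["confidence"], conf)
        else:
            net.add_edge(a, b, confidence=conf)
    net.add_nodes_from(n for n in extra_nodes)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", name, n_loops)
    return net


def read_interactions(
    path: str | Path,
    dialect: str = "string_tsv",
    score_cutoff: float = 0.5,
) -> InteractionNetwork:
    """Read a weighted interaction network, keeping edges with confidence >= cutoff.

    Parameters
    ----------
    path:
        Edge-list file in the given dialect.
    dialect:
        One of ``string_tsv`` (whitespace-separated, optional header),
        ``plain_tsv`` (tab-separated, optional header), ``sif`` or ``graphml``.
    score_cutoff:
        Inclusive confidence threshold on the normalised 0-1 scale.
    """
    if not 0.0 <= score_cutoff <= 1.0:
        raise ConfigurationError(f"score_cutoff {score_cutoff} outside [0, 1]")
    if dialect not in INTERACTION_DIALECTS:
        raise ConfigurationError(
            f"unknown interaction dialect {dialect!r}; expected one of {INTERACTION_DIALECTS}"
        )
    path = Path(path)
    name = path.stem
    if dialect == "graphml":
        g = nx.read_graphml(path)
        pairs = [(str(a).upper(), str(b).upper()) for a, b in g.edges()]
        scores = [float(d.get("confidence", 1.0)) for _, _, d in g.edges(data=True)]
        confs = _normalise_scores(scores, str(path))
        extra = (str(n).upper() for n in g.nodes() if g.degree(n) == 0)
        return _build_network(pairs, confs, score_cutoff, name, extra)
    text = path.read_text().splitlines()
    if dialect == "sif":
        pairs, singles = _parse_sif(text, str(path))
        return _build_network(pairs, [1.0] * len(pairs), score_cutoff, name, singles)
    sep = "\t" if dialect == "plain_tsv" else None
    pairs, raw = _parse_edge_lines(text, str(path), sep)
    confs = _normalise_scores(raw, str(path))
    return _build_network(pairs, confs, score_cutoff, name)


def read_node_metadata(path: str | Path) -> dict[str, GeneNode]:
    """Read a TSV of per-gene metadata (columns id, symbol, description,
    disease_score; the score column may be empty)."""
    path = Path(path)
    nodes: dict[str, GeneNode] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "symbol", "description", "disease_score"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            gid = row["id"].strip().upper()
            if not gid:
                raise ParseError(f"{path}:{lineno}: empty gene id")
            if gid in nodes:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid}")
            raw_ds = (row.get("disease_score") or "").strip()
            ds = float(raw_ds) if raw_ds else None
            nodes[gid] = GeneNode(
                id=gid,
                symbol=row["symbol"].strip(),
                description=row["description"].strip(),
                disease_score=ds,
            )
    return nodes


def read_actions(path: str | Path, score_cutoff: float = 0.5) -> list[ActionEdge]:
    """Read a STRING-style actions table, keeping recognised modes with
    score >= cutoff.  Unrecognised modes are skipped (count logged); a file
    yielding no edges is a warning, not an error."""
    if not 0.0 <= score_cutoff <= 1.0:
        raise ConfigurationError(f"score_cutoff {score_cutoff} outside [0, 1]")
    path = Path(path)
    rows: list[tuple[str, str, str, float, bool]] = []
    raw_scores: list[float] = []
    n_unknown = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}")
        a, b, mode = fields[0].upper(), fields[1].upper(), fields[2].lower()
        try:
            score = float(fields[3])
        except ValueError:
            if lineno == 1:
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric score {fields[3]!r}") from None
        directed = len(fields) > 4 and fields[4].strip().lower() in {"t", "true", "1", "yes"}
        if mode not in ACTION_MODES:
            n_unknown += 1
            continue
        rows.append((a, b, mode, score, directed))
        raw_scores.append(score)
    if n_unknown:
        logger.info("%s: skipped %d row(s) with unrecognised action modes", path, n_unknown)
    confs = _normalise_scores(raw_scores, str(path))
    edges = [
        ActionEdge(source=a, target=b, mode=m, score=c, directed=d)
        for (a, b, m, _s, d), c in zip(rows, confs)
        if c >= score_cutoff
    ]
    if not edges:
        logger.warning("%s: no action edges passed the mode and score filters", path)
    return edges


def read_gene_sets(path: str | Path, dialect: str = "gmt") -> list[GeneSet]:
    """Read gene-set annotations.

    ``gmt`` lines are ``term_id<TAB>term_name<TAB>gene...``; the
    ``tsv_with_depth`` dialect inserts an integer ontology-depth column after
    the term name.  Gene ids are uppercased and deduplicated.
    """
    if dialect not in GENESET_DIALECTS:
        raise ConfigurationError(
            f"unknown gene-set dialect {dialect!r}; expected one of {GENESET_DIALECTS}"
        )
    path = Path(path)
    n_meta = 2 if dialect == "gmt" else 3
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < n_meta + 1:
            raise ParseError(
                f"{path}:{lineno}: expected at least {n_meta + 1} tab-separated fields"
            )
        term_id, term_name = fields[0], fields[1]
        depth: int | None = None
        if dialect == "tsv_with_depth":
            try:
                depth = int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer depth {fields[2]!r}") from None
        genes = frozenset(g.strip().upper() for g in fields[n_meta:] if g.strip())
        if not genes:
            raise ParseError(f"{path}:{lineno}: term {term_id} has no genes")
        sets.append(GeneSet(term_id=term_id, term_name=term_name, genes=genes, depth=depth))
    return sets


def write_network(net: InteractionNetwork, path: str | Path, dialect: str = "plain_tsv") -> None:
    """Write a network so that re-reading it recovers the node and edge sets.

    ``plain_tsv`` and ``string_tsv`` hold only edges, so isolated nodes do not
    survive a round trip in those dialects; SIF writes them as lone-node lines
    and GraphML keeps everything.
    """
    path = Path(path)
    if dialect in ("plain_tsv", "string_tsv"):
        with path.open("w") as fh:
            fh.write("node_a\tnode_b\tcombined_score\n")
            for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
                conf = net[a][b].get("confidence", 1.0)
                if dialect == "string_tsv":
                    fh.write(f"{a}\t{b}\t{int(round(conf * 1000))}\n")
                else:
                    fh.write(f"{a}\t{b}\t{conf:.6f}\n")
    elif dialect == "sif":
        with path.open("w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
                fh.write(f"{a}\tinteracts\t{b}\n")
            for n in sorted(net.nodes()):
                if net.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif dialect == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ConfigurationError(f"unknown output dialect {dialect!r}")


def write_actions(edges: Sequence[ActionEdge], path: str | Path) -> None:
    """Write an actions table in the five-column dialect ``read_actions`` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("item_a\titem_b\tmode\tscore\tdirected\n")
        for e in edges:
            fh.write(
                f"{e.source}\t{e.target}\t{e.mode}\t{e.score:.6f}\t"
                f"{'true' if e.directed else 'false'}\n"
            )


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path, dialect: str = "gmt") -> None:
    """Write annotations in GMT or the depth-augmented TSV dialect."""
    if dialect not in GENESET_DIALECTS:
        raise ConfigurationError(f"unknown gene-set dialect {dialect!r}")
    path = Path(path)
    with path.open("w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            if dialect == "gmt":
                fh.write(f"{s.term_id}\t{s.term_name}\t{genes}\n")
            else:
                depth = s.depth if s.depth is not None else 0
                fh.write(f"{s.term_id}\t{s.term_name}\t{depth}\t{genes}\n")


def write_node_metadata(nodes: Mapping[str, GeneNode], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tsymbol\tdescription\tdisease_score\n")
        for gid in sorted(nodes):
            n = nodes[gid]
            ds = "" if n.disease_score is None else format_score(n.disease_score)
            fh.write(f"{n.id}\t{n.symbol}\t{n.description}\t{ds}\n")


def format_score(x: float) -> str:
    """Compact numeric formatting: integers without a trailing .0."""
    if math.isclose(x, round(x)):
        return str(int(round(x)))
    return f"{x:g}"
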