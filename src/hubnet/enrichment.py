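"""Gene-set enrichment with kappa-grouped terms.

For a query panel of n genes inside a universe of N genes, a term annotating
K universe genes and containing k of the query is tested two-sidedly against
Hypergeometric(N, K, n): the smaller of the upper tail P[X >= k] and lower
tail P[X <= k] is doubled (capped at 1), and the direction (enriched /
depleted) is whichever tail is smaller.  P-values are corrected across all
tested terms by the Bonferroni step-down (Holm) procedure.  A term passes
the report filters when it has at least ``min_genes`` query genes, covers at
least ``min_pct`` percent of its own annotation, reaches corrected
significance, and — when an ontology depth is known — lies inside the
``level_min``..``level_max`` depth window.

Passing terms are linked whenever the Cohen kappa agreement of their gene
memberships (over the union of all passing terms' genes) reaches a
threshold, and the connected components of that kappa graph form the term
groups, each led by its lowest-p term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .network_io import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Report thresholds; defaults follow standard ClueGO-style settings."""

    alpha: float = 0.05
    min_genes: int = 3
    min_pct: float = 4.0
    level_min: int = 2
    level_max: int = 8
    kappa_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1]")
        if not 0 <= self.kappa_threshold <= 1:
            raise ValidationError(f"kappa_threshold {self.kappa_threshold} outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    term: GeneSet
    k: int
    K: int
    n: int
    N: int
    direction: str
    p_value: float
    p_corrected: float
    pct_of_term: float
    passes_filters: bool


@dataclass(frozen=True)
class TermGroup:
    members: frozenset[str]
    leading_term: str
    group_kappa_threshold: float


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if N < 1:
        raise ValidationError("universe size N must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValidationError(f"k={k} impossible for K={K}, n={n}, N={N}")


def hypergeometric_two_sided(k: int, K: int, n: int, N: int) -> tuple[str, float]:
    """Two-sided hypergeometric test; returns (direction, p).

    The p-value doubles the smaller tail probability (capped at 1); the
    direction is ``enriched`` when the upper tail is the smaller (ties
    included), ``depleted`` otherwise.
    """
    _check_counts(k, K, n, N)
    dist = hypergeom(N, K, n)
    p_upper = float(dist.sf(k - 1))  # P[X >= k]
    p_lower = float(dist.cdf(k))  # P[X <= k]
    # exact tail ties (symmetric cases) count as enrichment; the tolerance
    # absorbs float noise in the tail sums
    if math.isclose(p_upper, p_lower, rel_tol=1e-9, abs_tol=1e-300):
        direction = "enriched"
    else:
        direction = "enriched" if p_upper < p_lower else "depleted"
    return direction, min(1.0, 2.0 * min(p_upper, p_lower))


def bonferroni_step_down(p_values: Sequence[float]) -> list[float]:
    """Holm step-down correction, returned in the input order."""
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p_values) == 0:
        return []
    return list(multipletests(list(p_values), method="holm")[1])


def kappa_score(term_a: GeneSet, term_b: GeneSet, universe: Iterable[str]) -> float:
    """Cohen's kappa of the two terms' gene memberships over *universe*.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|, d = |neither| (all within the
    universe): observed agreement (a+d)/N against the chance agreement of the
    marginals; returns 1 when the expected agreement is exactly 1.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValidationError("kappa universe is empty")
    A = term_a.genes & uni
    B = term_b.genes & uni
    N = len(uni)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    observed = (a + d) / N
    expected = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if expected == 1.0:
        return 1.0
    return (observed - expected) / (1.0 - expected)


def run_enrichment(
    query: Iterable[str],
    annotation: Sequence[GeneSet],
    universe: Iterable[str],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Test every term, Holm-correct across all of them, and apply filters.

    Query genes outside the universe are dropped (count logged); term sizes
    are likewise restricted to the universe.  Results come back in the order
    of *annotation*.
    """
    uni = frozenset(g.upper() for g in universe)
    if not uni:
        raise ValidationError("universe is empty")
    raw_query = frozenset(g.upper() for g in query)
    q = raw_query & uni
    dropped = len(raw_query) - len(q)
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    if not q:
        raise ValidationError("query is empty after restriction to the universe")
    N, n = len(uni), len(q)
    tested: list[tuple[GeneSet, int, int, str, float]] = []
    for term in annotation:
        genes = term.genes & uni
        K, k = len(genes), len(genes & q)
        direction, p = hypergeometric_two_sided(k, K, n, N)
        tested.append((term, k, K, direction, p))
    corrected = bonferroni_step_down([p for *_, p in tested])
    results: list[EnrichmentResult] = []
    for (term, k, K, direction, p), p_corr in zip(tested, corrected):
        pct = 100.0 * k / K if K else 0.0
        in_level = (
            term.depth is None or config.level_min <= term.depth <= config.level_max
        )
        passes = (
            k >= config.min_genes
            and pct >= config.min_pct
            and p_corr < config.alpha
            and in_level
        )
        results.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N, direction=direction,
                p_value=p, p_corrected=float(p_corr), pct_of_term=pct,
                passes_filters=bool(passes),
            )
        )
    return results


def group_terms(
    results: Sequence[EnrichmentResult], kappa_threshold: float = 0.5
) -> list[TermGroup]:
    """Group passing terms by connected components of the kappa graph.

    The kappa universe is the union of the passing terms' genes.  Each group
    is led by its lowest-corrected-p member (ties by term id); groups are
    returned ordered by (leading term's corrected p, leading term id).
    """
    if not 0.0 <= kappa_threshold <= 1.0:
        raise ValidationError(f"kappa_threshold {kappa_threshold} outside [0, 1]")
    passing = [r for r in results if r.passes_filters]
    if not passing:
        return []
    universe = frozenset().union(*(r.term.genes for r in passing))
    g = nx.Graph()
    g.add_nodes_from(r.term.term_id for r in passing)
    for i, ri in enumerate(passing):
        for rj in passing[i + 1 :]:
            if kappa_score(ri.term, rj.term, universe) >= kappa_threshold:
                g.add_edge(ri.term.term_id, rj.term.term_id)
    by_id = {r.term.term_id: r for r in passing}
    groups = []
    for comp in nx.connected_components(g):
        leader = min(comp, key=lambda t: (by_id[t].p_corrected, t))
        groups.append(
            TermGroup(
                members=frozenset(comp),
                leading_term=leader,
                group_kappa_threshold=kappa_threshold,
            )
        )
    groups.sort(key=lambda grp: (by_id[grp.leading_term].p_corrected, grp.leading_term))
    return groups


def write_enrichment_report(
    results: Sequence[EnrichmentResult],
    groups: Sequence[TermGroup],
    path: str | Path,
) -> None:
    """Report TSV sorted by corrected p, with group membership columns."""
    group_of: dict[str, int] = {}
    leaders: set[str] = set()
    for gi, grp in enumerate(groups, start=1):
        leaders.add(grp.leading_term)
        for t in grp.members:
            group_of[t] = gi
    rows = []
    for r in sorted(results, key=lambda r: (r.p_corrected, r.term.term_id)):
        t = r.term.term_id
        rows.append(
            {
                "term_id": t,
                "term_name": r.term.term_name,
                "namespace": r.term.namespace,
                "k": r.k,
                "K": r.K,
                "pct_of_term": f"{r.pct_of_term:.2f}",
                "direction": r.direction,
                "p_value": f"{r.p_value:.6g}",
                "p_corrected": f"{r.p_corrected:.6g}",
                "passes_filters": r.passes_filters,
                "group_id": group_of.get(t, ""),
                "is_leading_term": t in leaders,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
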