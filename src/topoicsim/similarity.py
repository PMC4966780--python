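"""The TopoICSim term- and gene-level similarity.

For two terms t1, t2 and each disjunctive common ancestor x the distance
is the ratio of the length-weighted minimum-IIC path t1 -> x <- t2 (the
hinge x counted once) to the length-weighted maximum-IIC path x -> root:

    D(t1, t2, x) = wSP(t1, t2, x) / wLP(x, root)

The term distance D(t1, t2) is the minimum of D(t1, t2, x) over all
disjunctive common ancestors, with D = 0 for identical terms and
D = +inf when the only disjunctive common ancestor is the aspect root.
Distances map to similarities in [0, 1] through

    S(t1, t2) = 1 - arctan(D(t1, t2)) / (pi/2).

Gene-level similarity aggregates the n x m matrix of term similarities
between the two genes' annotation sets, by default with rcmax (the larger
of the two directional best-match averages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .go_dag_io import AnnotationCorpus, OntologyGraph
from .info_content import (
    ICTable,
    _contrib,
    weighted_longest_path_to_root,
    weighted_shortest_path,
)

AGGREGATORS = ("rcmax", "avg", "bma")


@dataclass(frozen=True)
class TermPairResult:
    """Distance and similarity for one term pair."""

    t1: str
    t2: str
    distance: float
    similarity: float
    chosen_ancestor: str | None


def similarity_from_distance(distance: float) -> float:
    """Map a distance in [0, +inf] to a similarity in [0, 1] via arctan."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if math.isinf(distance):
        return 0.0
    return 1.0 - math.atan(distance) / (math.pi / 2.0)


def term_distance_via_ancestor(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str, ancestor: str
) -> float:
    """D(t1, t2, x) for one disjunctive common ancestor x.

    The combined through-ancestor path sums the two one-sided minimum-IIC
    paths with the hinge's 1/IC counted once; its weight is the combined
    IIC times the combined edge count.  Returns +inf when the longest
    root path has zero weight (x is the aspect root).
    """
    if ancestor not in graph.disjunctive_common_ancestors(t1, t2):
        raise ValueError(
            f"{ancestor!r} is not a disjunctive common ancestor of "
            f"({t1!r}, {t2!r})"
        )
    wsp, _ = _combined_shortest(graph, ic, t1, t2, ancestor)
    wlp = weighted_longest_path_to_root(graph, ic, ancestor).weighted
    if wlp == 0.0:
        return math.inf
    return wsp / wlp


def _combined_shortest(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str, ancestor: str
) -> tuple[float, float]:
    """(weighted value, IIC) of the combined path t1 -> x <- t2."""
    root = graph.root_of(ancestor)
    sp1 = weighted_shortest_path(graph, ic, t1, ancestor)
    sp2 = weighted_shortest_path(graph, ic, t2, ancestor)
    iic = sp1.iic + sp2.iic - _contrib(ancestor, ic, root)  # hinge once
    length = sp1.path.length + sp2.path.length
    return iic * length, iic


def term_distance(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> TermPairResult:
    """Minimum of D(t1, t2, x) over all disjunctive common ancestors.

    Ties are broken toward the smaller combined shortest-path weight, then
    the lexicographically smallest ancestor ID.
    """
    if t1 == t2:
        return TermPairResult(t1, t2, 0.0, 1.0, t1)
    root = graph.root_of(t1)
    dca = graph.disjunctive_common_ancestors(t1, t2)
    if dca == {root}:
        return TermPairResult(t1, t2, math.inf, 0.0, None)

    best: tuple[float, float, str] | None = None
    for x in sorted(dca):
        wsp, _ = _combined_shortest(graph, ic, t1, t2, x)
        wlp = weighted_longest_path_to_root(graph, ic, x).weighted
        d = math.inf if wlp == 0.0 else wsp / wlp
        key = (d, wsp, x)
        if best is None or key < best:
            best = key
    d, _wsp, x = best
    return TermPairResult(t1, t2, d, similarity_from_distance(d), x)


def term_similarity(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> TermPairResult:
    """S(t1, t2) = 1 - arctan(D(t1, t2)) / (pi/2)."""
    return term_distance(graph, ic, t1, t2)


class TermSimilarityCache:
    """Memoises term-pair similarities; the key is the unordered pair."""

    def __init__(self, graph: OntologyGraph, ic: ICTable):
        self.graph = graph
        self.ic = ic
        self._cache: dict[frozenset[str], float] = {}

    def similarity(self, t1: str, t2: str) -> float:
        key = frozenset((t1, t2))
        if key not in self._cache:
            self._cache[key] = term_similarity(self.graph, self.ic, t1, t2).similarity
        return self._cache[key]


def similarity_matrix(
    graph: OntologyGraph,
    ic: ICTable,
    terms1: list[str],
    terms2: list[str],
    cache: TermSimilarityCache | None = None,
) -> np.ndarray:
    """The n x m matrix s_ij of term similarities between two term lists."""
    cache = cache or TermSimilarityCache(graph, ic)
    out = np.empty((len(terms1), len(terms2)))
    for i, a in enumerate(terms1):
        for j, b in enumerate(terms2):
            out[i, j] = cache.similarity(a, b)
    return out


def aggregate_matrix(s: np.ndarray, aggregator: str = "rcmax") -> float:
    """Collapse a term-similarity matrix to one gene-level score.

    rcmax = max(mean of row maxima, mean of column maxima);
    bma   = mean of those two directional best-match averages;
    avg   = grand mean.
    """
    if s.size == 0:
        raise ValueError("empty similarity matrix")
    if aggregator == "avg":
        return float(s.mean())
    row_best = float(s.max(axis=1).mean())
    col_best = float(s.max(axis=0).mean())
    if aggregator == "rcmax":
        return max(row_best, col_best)
    if aggregator == "bma":
        return (row_best + col_best) / 2.0
    raise ValueError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")


def gene_similarity(
    graph: OntologyGraph,
    ic: ICTable,
    corpus: AnnotationCorpus,
    g1: str,
    g2: str,
    aspect: str = "BP",
    aggregator: str = "rcmax",
    cache: TermSimilarityCache | None = None,
) -> float:
    """TopoICSim similarity of two genes over one aspect, in [0, 1]."""
    terms1 = corpus.terms_of(g1, graph, aspect)
    terms2 = corpus.terms_of(g2, graph, aspect)
    s = similarity_matrix(graph, ic, terms1, terms2, cache)
    return aggregate_matrix(s, aggregator)


def pairwise_matrix(
    graph: OntologyGraph,
    ic: ICTable,
    corpus: AnnotationCorpus,
    genes: list[str],
    aspect: str = "BP",
    aggregator: str = "rcmax",
    cache: TermSimilarityCache | None = None,
):
    """Symmetric gene x gene similarity matrix as a pandas DataFrame.

    Term-pair similarities are shared through a single cache so each
    unordered term pair is scored once.
    """
    import pandas as pd

    if not genes:
        raise ValueError("need at least one gene")
    for g in genes:
        corpus.terms_of(g, graph, aspect)  # fail early, naming the gene
    cache = cache or TermSimilarityCache(graph, ic)
    n = len(genes)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                value = gene_similarity(
                    graph, ic, corpus, genes[i], genes[j], aspect, aggregator, cache
                )
            except (KeyError, ValueError) as exc:
                raise type(exc)(
                    f"gene pair ({genes[i]!r}, {genes[j]!r}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = value
    return pd.DataFrame(out, index=genes, columns=genes)
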