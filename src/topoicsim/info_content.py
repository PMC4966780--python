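"""Information content and IIC-weighted path selection.

The information content of a GO term t in an annotation corpus is

    IC(t) = -log(G_t / G_Tot)

where G_t is the number of genes annotated to t (by default after
propagating every annotation to all ancestors of its term) and G_Tot is
the size of the gene universe.  The inverse information content of a path
is IIC(P) = sum over path nodes of 1/IC(t); the aspect root, terms with
IC = 0 and unannotated terms (IC = +inf) contribute 0.

TopoICSim weights paths by their edge count *after* IIC-based selection:
the shortest path minimises IIC (found with a Dijkstra on node weights
1/IC), the longest path to the root maximises IIC (found by dynamic
programming in topological order).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import networkx as nx

from .go_dag_io import AnnotationCorpus, OntologyGraph, TermPath, UnknownTermError


@dataclass
class ICTable:
    """term -> information content (nats by default), plus G_Tot."""

    ic: dict[str, float]
    total_genes: int

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tic\n")
            for term in sorted(self.ic):
                fh.write(f"{term}\t{self.ic[term]!r}\n")

    @classmethod
    def from_tsv(cls, path, total_genes: int = 1) -> "ICTable":
        ic: dict[str, float] = {}
        with open(path) as fh:
            header = next(fh)
            if not header.startswith("term"):
                raise ValueError("IC table must have a 'term\\tic' header")
            for line in fh:
                term, value = line.rstrip("\n").split("\t")
                ic[term] = float(value)
        return cls(ic=ic, total_genes=total_genes)


@dataclass(frozen=True)
class WeightedPath:
    """A selected path with its IIC and length-weighted value."""

    path: TermPath
    iic: float

    @property
    def weighted(self) -> float:
        return self.iic * self.path.length


def compute_ic(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    log_base: float = math.e,
    propagate: bool = True,
) -> ICTable:
    """Per-term information content IC(t) = -log(G_t / G_Tot).

    With ``propagate`` (the default) a gene annotated to t counts for t
    and every ancestor of t, so counts are monotone non-decreasing toward
    the root and each aspect root that received any annotation gets IC 0.
    Terms with no (propagated) annotation get the +inf sentinel.
    """
    if corpus.total_genes <= 0 or not corpus.gene_terms:
        raise ValueError("annotation corpus is empty (G_Tot = 0)")
    if log_base <= 1:
        raise ValueError("log_base must be > 1")

    genes_at: dict[str, set[str]] = {t: set() for t in graph.dag.nodes}
    for gene, annots in corpus.gene_terms.items():
        for term, _ec in annots:
            if term in genes_at:
                genes_at[term].add(gene)
    if propagate:
        # child-before-parent order; union child sets into parents
        for node in nx.topological_sort(graph.dag):
            for parent in graph.dag.successors(node):
                genes_at[parent] |= genes_at[node]

    log_b = math.log(log_base)
    ic: dict[str, float] = {}
    for term, genes in genes_at.items():
        if not genes:
            ic[term] = math.inf
        else:
            ic[term] = -math.log(len(genes) / corpus.total_genes) / log_b
            if ic[term] == 0.0:
                ic[term] = 0.0  # normalise -0.0
    return ICTable(ic=ic, total_genes=corpus.total_genes)


def _contrib(term: str, ic: ICTable, root: str) -> float:
    """1/IC(term), with the root and IC in {0, +inf} contributing 0."""
    if term == root:
        return 0.0
    value = ic[term]
    if value == 0.0 or math.isinf(value):
        return 0.0
    return 1.0 / value


def iic(path: TermPath | tuple[str, ...], ic: ICTable, root: str) -> float:
    """Inverse information content of a path: sum of 1/IC over its nodes.

    The aspect root is excluded; IC = 0 and IC = +inf nodes contribute 0.
    """
    nodes = path.nodes if isinstance(path, TermPath) else tuple(path)
    return sum(_contrib(t, ic, root) for t in nodes)


def weighted_shortest_path(
    graph: OntologyGraph, ic: ICTable, term: str, ancestor: str
) -> WeightedPath:
    """Minimum-IIC upward path ``term -> ancestor`` (Dijkstra).

    The node-weighted problem is solved as an edge-weighted one: edge
    (u -> v) carries 1/IC(v) and the start node's 1/IC is added once.
    Ties on IIC are broken toward shorter length, then lexicographically
    smallest node sequence, so selection is deterministic.  The weighted
    value is IIC x edge count, applied after selection.
    """
    if term not in graph or ancestor not in graph:
        raise UnknownTermError(f"unknown term in ({term!r}, {ancestor!r})")
    root = graph.root_of(term)
    start = (_contrib(term, ic, root), 0, (term,))
    # heap keys (iic, length, nodes) give Dijkstra on iic with the
    # stated deterministic tie-breaks
    heap: list[tuple[float, int, tuple[str, ...]]] = [start]
    settled: set[str] = set()
    while heap:
        cost, length, nodes = heapq.heappop(heap)
        node = nodes[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == ancestor:
            return WeightedPath(path=TermPath(nodes), iic=cost)
        for parent in graph.dag.successors(node):
            if parent not in settled:
                heapq.heappush(
                    heap,
                    (cost + _contrib(parent, ic, root), length + 1, nodes + (parent,)),
                )
    raise ValueError(f"{ancestor!r} is not an ancestor of {term!r}")


def weighted_longest_path_to_root(
    graph: OntologyGraph, ic: ICTable, term: str
) -> WeightedPath:
    """Maximum-IIC upward path ``term -> aspect root``.

    Computed by dynamic programming over a topological order of the
    ancestor subgraph.  Ties on IIC are broken toward longer length, then
    lexicographically smallest node sequence.  The root is excluded from
    the IIC sum but its edge counts toward the length.
    """
    if term not in graph:
        raise UnknownTermError(f"unknown term {term!r}")
    root = graph.root_of(term)
    allowed = graph.ancestors(term) | {term}
    if root not in allowed:
        raise ValueError(f"term {term!r} is disconnected from root {root!r}")
    sub = graph.dag.subgraph(allowed)

    best: dict[str, tuple[float, int, tuple[str, ...]]] = {
        term: (_contrib(term, ic, root), 0, (term,))
    }
    for node in nx.topological_sort(sub):
        if node not in best:
            continue  # not reachable upward from term
        cost, length, nodes = best[node]
        for parent in sub.successors(node):
            cand = (cost + _contrib(parent, ic, root), length + 1, nodes + (parent,))
            cur = best.get(parent)
            if cur is None or _lp_better(cand, cur):
                best[parent] = cand
    cost, _length, nodes = best[root]
    return WeightedPath(path=TermPath(nodes), iic=cost)


def _lp_better(
    cand: tuple[float, int, tuple[str, ...]],
    cur: tuple[float, int, tuple[str, ...]],
) -> bool:
    if cand[0] != cur[0]:
        return cand[0] > cur[0]
    if cand[1] != cur[1]:
        return cand[1] > cur[1]
    return cand[2] < cur[2]
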