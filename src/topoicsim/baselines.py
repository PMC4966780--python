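"""Five published gene-similarity measures used for comparison.

IntelliGO (cosine of annotation vectors with LCA-depth basis products),
Wang (semantic-contribution S-values with BMA aggregation), Resnik/Lord
(IC of the deepest common ancestor, averaged over the term grid),
Al-Mubaid (exponential of the mean shortest path length) and SimGIC
(IC-weighted Jaccard over annotation ancestor closures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .go_dag_io import AnnotationCorpus, OntologyGraph
from .info_content import ICTable


@dataclass(frozen=True)
class LcaInfo:
    """Deepest common ancestor with its depth and the shortest
    through-LCA path length between the two query terms (in edges)."""

    lca: str
    depth: int
    min_spl_through_lca: int


def _upward_dists(graph: OntologyGraph, term: str) -> dict[str, int]:
    """Shortest upward distance (edges) from ``term`` to each ancestor."""
    return nx.single_source_shortest_path_length(graph.dag, term)


def lca_info(graph: OntologyGraph, t1: str, t2: str) -> LcaInfo:
    """LCA = common ancestor of maximum depth (longest root path), ties
    broken lexicographically; MinSPL = shortest t1->lca plus t2->lca."""
    com = graph.common_ancestors(t1, t2)
    lca = max(sorted(com), key=lambda x: graph.depth(x))
    d1 = _upward_dists(graph, t1)
    d2 = _upward_dists(graph, t2)
    return LcaInfo(lca=lca, depth=graph.depth(lca),
                   min_spl_through_lca=d1[lca] + d2[lca])


# ---------------------------------------------------------------------
# IntelliGO
# ---------------------------------------------------------------------

def _propagated_counts(graph: OntologyGraph, corpus: AnnotationCorpus) -> dict[str, int]:
    genes_at: dict[str, set[str]] = {t: set() for t in graph.dag.nodes}
    for gene, annots in corpus.gene_terms.items():
        for term, _ec in annots:
            if term in genes_at:
                genes_at[term].add(gene)
    for node in nx.topological_sort(graph.dag):
        for parent in graph.dag.successors(node):
            genes_at[parent] |= genes_at[node]
    return {t: len(g) for t, g in genes_at.items()}


def _basis_dot(graph: OntologyGraph, t1: str, t2: str) -> float:
    """e_i . e_j = 2 Depth(LCA) / (MinSPL + 2 Depth(LCA)); 1 for t1 = t2
    (and for the 0/0 root-root case)."""
    if t1 == t2:
        return 1.0
    info = lca_info(graph, t1, t2)
    denom = info.min_spl_through_lca + 2 * info.depth
    if denom == 0:
        return 1.0
    return 2.0 * info.depth / denom


def sim_intelligo(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    g1: str,
    g2: str,
    aspect: str = "BP",
    ec_weights: dict[str, float] | None = None,
) -> float:
    """IntelliGO cosine similarity of evidence-weighted annotation vectors.

    Coefficients are alpha_i = w(g, t_i) x IFA(t_i) with IFA the inverse
    annotation frequency log(G_Tot / G_t) (0 at the root); evidence-code
    weights default to 1 for every code.
    """
    counts = _propagated_counts(graph, corpus)
    ec_weights = ec_weights or {}

    def coeffs(gene: str) -> dict[str, float]:
        if gene not in corpus.gene_terms:
            raise KeyError(f"gene {gene!r} not found in annotation corpus")
        out: dict[str, float] = {}
        for term, ec in corpus.gene_terms[gene]:
            if term not in graph.dag.nodes or graph.aspect_of(term) != aspect:
                continue
            ifa = math.log(corpus.total_genes / counts[term]) if counts[term] else 0.0
            w = ec_weights.get(ec, 1.0)
            out[term] = max(out.get(term, 0.0), w * ifa)
        if not out:
            raise ValueError(f"gene {gene!r} unannotated in aspect {aspect}")
        return out

    a, b = coeffs(g1), coeffs(g2)

    def dot(u: dict[str, float], v: dict[str, float]) -> float:
        return sum(
            au * bv * _basis_dot(graph, ta, tb)
            for ta, au in u.items() for tb, bv in v.items()
        )

    denom = math.sqrt(dot(a, a)) * math.sqrt(dot(b, b))
    if denom == 0.0:
        # all-root (zero-IFA) vectors carry no information
        return 1.0 if set(a) == set(b) else 0.0
    return dot(a, b) / denom


# ---------------------------------------------------------------------
# Wang
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class WangSValues:
    """Semantic contributions of a term's ancestor closure and their sum."""

    term: str
    s_contrib: dict[str, float]
    sv: float


def wang_s_values(
    graph: OntologyGraph, term: str, w_is_a: float = 0.8, w_part_of: float = 0.6
) -> WangSValues:
    """S-values of Wang et al.: S_t(t) = 1 and, walking upward,
    S_t(x) = max over children c of x inside t's closure of w_e x S_t(c)."""
    for w in (w_is_a, w_part_of):
        if not 0.0 < w <= 1.0:
            raise ValueError("edge weights must lie in (0, 1]")
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    closure = graph.ancestors(term) | {term}
    sub = graph.dag.subgraph(closure)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child in sub.predecessors(node):
            if child in s:
                w = weights[graph.dag.edges[child, node]["relation"]]
                best = max(best, w * s[child])
        if best > 0.0:
            s[node] = best
    return WangSValues(term=term, s_contrib=s, sv=sum(s.values()))


def wang_term_similarity(
    graph: OntologyGraph, t1: str, t2: str,
    w_is_a: float = 0.8, w_part_of: float = 0.6,
) -> float:
    sv1 = wang_s_values(graph, t1, w_is_a, w_part_of)
    sv2 = wang_s_values(graph, t2, w_is_a, w_part_of)
    common = set(sv1.s_contrib) & set(sv2.s_contrib)
    num = sum(sv1.s_contrib[x] + sv2.s_contrib[x] for x in common)
    return num / (sv1.sv + sv2.sv)


def sim_wang(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    g1: str,
    g2: str,
    aspect: str = "BP",
    w_is_a: float = 0.8,
    w_part_of: float = 0.6,
) -> float:
    """Wang gene similarity: best-match average of term-level scores."""
    terms1 = corpus.terms_of(g1, graph, aspect)
    terms2 = corpus.terms_of(g2, graph, aspect)
    s = [[wang_term_similarity(graph, a, b, w_is_a, w_part_of) for b in terms2]
         for a in terms1]
    row_best = sum(max(row) for row in s)
    col_best = sum(max(s[i][j] for i in range(len(terms1)))
                   for j in range(len(terms2)))
    return (row_best + col_best) / (len(terms1) + len(terms2))


# ---------------------------------------------------------------------
# Resnik / Lord
# ---------------------------------------------------------------------

def sim_resnik(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str, max_ic: bool = False
) -> float:
    """IC of the LCA; with ``max_ic`` the maximum IC over all common
    ancestors is used instead of the deepest ancestor's IC."""
    if max_ic:
        com = graph.common_ancestors(t1, t2)
        finite = [ic[x] for x in com if not math.isinf(ic[x])]
        return max(finite) if finite else 0.0
    value = ic[lca_info(graph, t1, t2).lca]
    return value


def sim_lord(
    graph: OntologyGraph,
    ic: ICTable,
    corpus: AnnotationCorpus,
    g1: str,
    g2: str,
    aspect: str = "BP",
    max_ic: bool = False,
) -> float:
    """Mean Resnik similarity over the full n x m term grid."""
    terms1 = corpus.terms_of(g1, graph, aspect)
    terms2 = corpus.terms_of(g2, graph, aspect)
    total = sum(
        sim_resnik(graph, ic, a, b, max_ic) for a in terms1 for b in terms2
    )
    return total / (len(terms1) * len(terms2))


# ---------------------------------------------------------------------
# Al-Mubaid
# ---------------------------------------------------------------------

def shortest_path_length(graph: OntologyGraph, t1: str, t2: str) -> int:
    """Shortest t1 -> x <- t2 path length in edges, over all common
    ancestors x."""
    d1 = _upward_dists(graph, t1)
    d2 = _upward_dists(graph, t2)
    return min(d1[x] + d2[x] for x in graph.common_ancestors(t1, t2))


def sim_mubaid(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    g1: str,
    g2: str,
    aspect: str = "BP",
    alpha: float = 0.2,
) -> float:
    """exp(-alpha x mean shortest path length over the term grid)."""
    terms1 = corpus.terms_of(g1, graph, aspect)
    terms2 = corpus.terms_of(g2, graph, aspect)
    pl = sum(
        shortest_path_length(graph, a, b) for a in terms1 for b in terms2
    ) / (len(terms1) * len(terms2))
    return math.exp(-alpha * pl)


# ---------------------------------------------------------------------
# SimGIC
# ---------------------------------------------------------------------

def sim_simgic(
    graph: OntologyGraph,
    ic: ICTable,
    corpus: AnnotationCorpus,
    g1: str,
    g2: str,
    aspect: str = "BP",
) -> float:
    """IC-weighted Jaccard over the genes' annotation ancestor closures.

    Terms with IC = +inf are excluded from both sums; an empty (all-zero)
    union is scored 0.
    """
    def closure(gene: str) -> set[str]:
        terms = corpus.terms_of(gene, graph, aspect)
        out: set[str] = set()
        for t in terms:
            out |= graph.ancestors(t) | {t}
        return out

    c1, c2 = closure(g1), closure(g2)

    def ic_sum(terms: set[str]) -> float:
        # sorted so equal sets sum identically (exact 1.0 for g1 == g2)
        return sum(ic[t] for t in sorted(terms) if not math.isinf(ic[t]))

    union = ic_sum(c1 | c2)
    if union == 0.0:
        return 0.0
    return ic_sum(c1 & c2) / union


#: measure name -> gene-level callable signature marker (used by the CLI)
GENE_MEASURES = ("topoicsim", "intelligo", "wang", "lord", "mubaid", "simgic")
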