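"""Ontology and annotation I/O plus rooted-DAG topology primitives.

Each Gene Ontology aspect (biological process BP, molecular function MF,
cellular component CC) is modelled as a rooted directed acyclic graph
(rDAG) whose edges point child -> parent and carry a hierarchical relation
(``is_a`` or ``part_of``).  Annotations map gene identifiers to sets of
(term, evidence-code) pairs.

This module provides the parsers (OBO 1.2 via :mod:`obonet`, GAF 2.x) and
the topology primitives the similarity measures are built on: ancestor and
child queries, common and *disjunctive* common ancestors, and exhaustive
upward-path enumeration (oracle use only).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")

#: OBO namespace -> aspect code
_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

#: GAF column 9 letter -> aspect code
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}

#: hierarchical relations traversed by the similarity measures
HIERARCHICAL_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Malformed or empty ontology input."""


class UnknownTermError(KeyError):
    """A term identifier not present in the graph."""


class AspectMismatchError(ValueError):
    """Two terms from different ontology aspects were combined."""


class AnnotationError(ValueError):
    """Malformed or empty annotation input."""


@dataclass(frozen=True)
class TermPath:
    """An oriented path in the rDAG.

    ``nodes`` is the ordered node sequence; for ``orientation='upward'``
    every consecutive pair is a child -> parent edge, for
    ``'through-ancestor'`` the path climbs from one endpoint to a hinge
    node and descends to the other endpoint.
    """

    nodes: tuple[str, ...]
    orientation: str = "upward"

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1


@dataclass
class AnnotationCorpus:
    """gene -> {(term, evidence code)} plus the gene-universe size G_Tot."""

    gene_terms: dict[str, set[tuple[str, str]]]
    total_genes: int = 0

    def __post_init__(self) -> None:
        if self.total_genes <= 0:
            self.total_genes = len(self.gene_terms)
        if self.total_genes < len(self.gene_terms):
            raise AnnotationError(
                "total_genes smaller than the number of annotated genes"
            )

    def terms_of(self, gene: str, graph: "OntologyGraph", aspect: str) -> list[str]:
        """Sorted distinct terms annotated to ``gene`` in one aspect.

        Raises :class:`KeyError` for an unknown gene and
        :class:`AnnotationError` for a gene with no annotation in the
        requested aspect.
        """
        if gene not in self.gene_terms:
            raise KeyError(f"gene {gene!r} not found in annotation corpus")
        terms = sorted(
            {t for t, _ec in self.gene_terms[gene] if graph.aspect_of(t) == aspect}
        )
        if not terms:
            raise AnnotationError(f"gene {gene!r} unannotated in aspect {aspect}")
        return terms


@dataclass
class OntologyGraph:
    """One or more aspect rDAGs with child->parent edges.

    ``dag`` holds every term as a node (attributes ``name``, ``aspect``)
    and every hierarchical relation as an edge with a ``relation``
    attribute.  ``aspect_roots`` maps each present aspect to its root term
    (the aspect node itself, with no parent).
    """

    dag: nx.DiGraph
    aspect_roots: dict[str, str]
    _depths: dict[str, int] | None = field(default=None, repr=False, compare=False)

    # -- basic queries -------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self.dag

    def __len__(self) -> int:
        return self.dag.number_of_nodes()

    @property
    def terms(self) -> list[str]:
        return sorted(self.dag.nodes)

    def _require(self, term: str) -> None:
        if term not in self.dag:
            raise UnknownTermError(f"unknown term {term!r}")

    def aspect_of(self, term: str) -> str:
        self._require(term)
        return self.dag.nodes[term]["aspect"]

    def root_of(self, term: str) -> str:
        """The aspect root above ``term``."""
        return self.aspect_roots[self.aspect_of(term)]

    # -- topology primitives -------------------------------------------
    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term``, excluding itself."""
        self._require(term)
        return nx.descendants(self.dag, term)  # edges run child->parent

    def children(self, term: str) -> set[str]:
        """Immediate children (terms with an edge into ``term``)."""
        self._require(term)
        return set(self.dag.predecessors(term))

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self.dag.successors(term))

    def common_ancestors(self, t1: str, t2: str) -> set[str]:
        """(ancestors(t1) ∪ {t1}) ∩ (ancestors(t2) ∪ {t2}).

        A term counts as its own ancestor here so that identical terms and
        ancestor–descendant pairs behave.
        """
        if self.aspect_of(t1) != self.aspect_of(t2):
            raise AspectMismatchError(
                f"terms {t1!r} ({self.aspect_of(t1)}) and {t2!r} "
                f"({self.aspect_of(t2)}) are from different aspects"
            )
        return (self.ancestors(t1) | {t1}) & (self.ancestors(t2) | {t2})

    def disjunctive_common_ancestors(self, t1: str, t2: str) -> set[str]:
        """Minimal (most specific, mutually non-ancestral) common ancestors.

        These are the members of ``common_ancestors(t1, t2)`` none of whose
        immediate children also belong to the common-ancestor set — the
        antichain of the set under the ancestor partial order.
        """
        com = self.common_ancestors(t1, t2)
        if not com:
            raise OntologyError(f"{t1!r} and {t2!r} share no common ancestor")
        return {x for x in com if not (self.children(x) & com)}

    def enumerate_paths(
        self, term: str, ancestor: str, max_nodes: int = 16
    ) -> list[TermPath]:
        """Every upward path ``term -> ancestor`` (exponential; oracle use).

        Refuses graphs larger than ``max_nodes`` — use the Dijkstra /
        topological-order machinery in :mod:`topoicsim.info_content` for
        production-size ontologies.
        """
        self._require(term)
        self._require(ancestor)
        if len(self.dag) > max_nodes:
            raise OntologyError(
                f"graph has {len(self.dag)} nodes > max_nodes={max_nodes}; "
                "exhaustive path enumeration is for small oracle graphs only "
                "(use weighted_shortest_path / weighted_longest_path_to_root)"
            )
        if term == ancestor:
            return [TermPath((term,))]
        if ancestor not in self.ancestors(term):
            raise OntologyError(f"{ancestor!r} is not an ancestor of {term!r}")
        return [
            TermPath(tuple(p))
            for p in sorted(nx.all_simple_paths(self.dag, term, ancestor))
        ]

    # -- depths (longest root->term path, memoised) --------------------
    def depth(self, term: str) -> int:
        """Depth of ``term``: edge count of the longest upward path to root."""
        self._require(term)
        if self._depths is None:
            depths: dict[str, int] = {}
            for node in reversed(list(nx.topological_sort(self.dag))):
                ps = list(self.dag.successors(node))
                depths[node] = 1 + max(depths[p] for p in ps) if ps else 0
            self._depths = depths
        return self._depths[term]


def build_graph(
    nodes: dict[str, str],
    edges: list[tuple[str, str, str]],
    names: dict[str, str] | None = None,
) -> OntologyGraph:
    """Assemble an :class:`OntologyGraph` from ``{term: aspect}`` and
    ``(child, parent, relation)`` triples, validating the rDAG invariants."""
    dag = nx.DiGraph()
    names = names or {}
    for term, aspect in nodes.items():
        if aspect not in ASPECTS:
            raise OntologyError(f"unknown aspect {aspect!r} for term {term!r}")
        dag.add_node(term, aspect=aspect, name=names.get(term, term))
    for child, parent, relation in edges:
        for endpoint in (child, parent):
            if endpoint not in dag:
                raise OntologyError(f"edge endpoint {endpoint!r} is not a term")
        if dag.nodes[child]["aspect"] != dag.nodes[parent]["aspect"]:
            raise OntologyError(
                f"edge {child!r}->{parent!r} crosses aspects"
            )
        if relation not in HIERARCHICAL_RELATIONS:
            raise OntologyError(f"unknown relation {relation!r}")
        dag.add_edge(child, parent, relation=relation)
    if not dag:
        raise OntologyError("empty ontology")
    if not nx.is_directed_acyclic_graph(dag):
        raise OntologyError("ontology contains a cycle")
    roots = _find_aspect_roots(dag)
    return OntologyGraph(dag=dag, aspect_roots=roots)


def _find_aspect_roots(dag: nx.DiGraph) -> dict[str, str]:
    roots: dict[str, str] = {}
    for aspect in ASPECTS:
        members = [n for n, d in dag.nodes(data=True) if d["aspect"] == aspect]
        if not members:
            continue
        parentless = sorted(n for n in members if dag.out_degree(n) == 0)
        if len(parentless) == 1:
            roots[aspect] = parentless[0]
        else:
            # several parentless terms (e.g. after relation filtering):
            # take the one dominating the largest subgraph and warn
            best = max(
                parentless, key=lambda n: (len(nx.ancestors(dag, n)), n)
            )
            logger.warning(
                "aspect %s has %d parentless terms %s; using %s as root",
                aspect, len(parentless), parentless, best,
            )
            roots[aspect] = best
    return roots


# ---------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------

def parse_obo(stream, aspect_filter: str | None = None) -> OntologyGraph:
    """Parse an OBO 1.2 document into an :class:`OntologyGraph`.

    ``stream`` may be a path, a text file object, or an OBO document as a
    string.  Only ``is_a`` and ``relationship: part_of`` edges are kept;
    other relations (``regulates`` family etc.) are dropped with a logged
    count, cross-aspect edges are dropped, and obsolete terms never enter
    the graph.  ``aspect_filter`` restricts the result to one aspect.
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    try:
        multi = obonet.read_obo(stream, ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise OntologyError(f"malformed OBO input: {exc}") from exc

    nodes: dict[str, str] = {}
    names: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        aspect = _NAMESPACE_TO_ASPECT.get(data.get("namespace", ""))
        if aspect is None:
            continue
        if aspect_filter is not None and aspect != aspect_filter:
            continue
        nodes[term] = aspect
        names[term] = data.get("name", term)

    edges: list[tuple[str, str, str]] = []
    n_dropped_rel = n_dropped_cross = 0
    for child, parent, relation in multi.edges(keys=True):
        if relation not in HIERARCHICAL_RELATIONS:
            n_dropped_rel += 1
            continue
        if child not in nodes or parent not in nodes:
            continue
        if nodes[child] != nodes[parent]:
            n_dropped_cross += 1
            continue
        edges.append((child, parent, relation))
    if n_dropped_rel:
        logger.info("dropped %d non-hierarchical relation edges", n_dropped_rel)
    if n_dropped_cross:
        logger.info("dropped %d cross-aspect edges", n_dropped_cross)

    if not nodes:
        raise OntologyError(
            "empty ontology"
            + (f" after filtering to aspect {aspect_filter}" if aspect_filter else "")
        )
    return build_graph(nodes, edges, names)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialise the graph back to a minimal OBO 1.2 document."""
    aspect_ns = {v: k for k, v in _NAMESPACE_TO_ASPECT.items()}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in graph.terms:
            data = graph.dag.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {aspect_ns[data['aspect']]}\n")
            for parent in sorted(graph.dag.successors(term)):
                rel = graph.dag.edges[term, parent]["relation"]
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


# ---------------------------------------------------------------------
# GAF parsing
# ---------------------------------------------------------------------

def parse_gaf(
    stream,
    graph: OntologyGraph,
    evidence_filter: set[str] | None = None,
    aspect: str = "BP",
    aliases: dict[str, str] | None = None,
    total_genes: int | None = None,
) -> AnnotationCorpus:
    """Parse a GAF 2.x annotation file into an :class:`AnnotationCorpus`.

    Keeps rows of the requested ``aspect`` whose evidence code passes
    ``evidence_filter`` (default: all codes).  Rows qualified with NOT are
    excluded, and rows referencing terms absent from ``graph`` are dropped
    with a logged count.  Gene IDs are taken verbatim from column 2 unless
    an ``aliases`` table maps them to canonical IDs.
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    aliases = aliases or {}

    gene_terms: dict[str, set[tuple[str, str]]] = {}
    n_unknown = 0
    try:
        for lineno, line in enumerate(stream, 1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise AnnotationError(
                    f"GAF line {lineno}: expected >=9 tab-separated columns"
                )
            gene, qualifier, term, evidence, asp = (
                cols[1], cols[3], cols[4], cols[6], cols[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            if _GAF_ASPECT.get(asp) != aspect:
                continue
            if evidence_filter is not None and evidence not in evidence_filter:
                continue
            if term not in graph:
                n_unknown += 1
                continue
            gene = aliases.get(gene, gene)
            gene_terms.setdefault(gene, set()).add((term, evidence))
    finally:
        if close:
            stream.close()

    if n_unknown:
        logger.warning("dropped %d annotation rows with unknown terms", n_unknown)
    if not gene_terms:
        raise AnnotationError("no annotations survived parsing/filtering")
    return AnnotationCorpus(gene_terms=gene_terms, total_genes=total_genes or 0)


def write_gaf(corpus: AnnotationCorpus, graph: OntologyGraph, path) -> None:
    """Serialise a corpus to GAF 2.2 (17 columns, '!'-prefixed header)."""
    aspect_letter = {v: k for k, v in _GAF_ASPECT.items()}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(corpus.gene_terms):
            for term, ec in sorted(corpus.gene_terms[gene]):
                asp = aspect_letter[graph.aspect_of(term)]
                cols = [
                    "SYNTH", gene, gene, "involved_in", term, "SYNTH:0",
                    ec, "", asp, gene, "", "gene", "taxon:0000",
                    "20160101", "SYNTH", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def read_alias_table(stream) -> dict[str, str]:
    """Read a 2-column (alias, canonical ID) TSV into a dict."""
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    try:
        out: dict[str, str] = {}
        for line in stream:
            if not line.strip() or line.startswith("#"):
                continue
            alias, canonical = line.rstrip("\n").split("\t")[:2]
            out[alias] = canonical
        return out
    finally:
        if close:
            stream.close()
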