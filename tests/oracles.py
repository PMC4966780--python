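"""Independent brute-force oracles used to validate the implementation.

Everything here works by exhaustive enumeration over small graphs and
stays deliberately independent of the package's production code paths:
only the graph container's raw edge structure and the exhaustive
`enumerate_paths` primitive are used.
"""

from __future__ import annotations

import math

from topoicsim.info_content import ICTable, iic
from topoicsim.go_dag_io import OntologyGraph


def upward_closure(graph: OntologyGraph, term: str) -> set[str]:
    """{term} plus every node reachable by child->parent edges (DFS)."""
    seen = {term}
    stack = [term]
    while stack:
        node = stack.pop()
        for parent in graph.dag.successors(node):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def common_ancestors_brute(graph: OntologyGraph, t1: str, t2: str) -> set[str]:
    return upward_closure(graph, t1) & upward_closure(graph, t2)


def disjunctive_brute(graph: OntologyGraph, t1: str, t2: str) -> set[str]:
    """Minimal-element filter over the exhaustive common-ancestor set."""
    com = common_ancestors_brute(graph, t1, t2)
    out = set()
    for x in com:
        others = com - {x}
        # x is minimal iff no other common ancestor lies strictly below it
        if not any(x in upward_closure(graph, y) - {y} for y in others):
            out.add(x)
    return out


def all_paths(graph: OntologyGraph, t: str, x: str) -> list[tuple[str, ...]]:
    return [p.nodes for p in graph.enumerate_paths(t, x, max_nodes=16)]


def best_side_path(
    graph: OntologyGraph, ic: ICTable, t: str, x: str, root: str, maximise: bool
) -> tuple[float, int]:
    """(IIC, length) of the min- (or max-) IIC path t->x, ties broken
    toward shorter (resp. longer) length."""
    cands = [(iic(p, ic, root), len(p) - 1) for p in all_paths(graph, t, x)]
    if maximise:
        return max(cands, key=lambda c: (c[0], c[1]))
    return min(cands, key=lambda c: (c[0], c[1]))


def _contrib(term: str, ic: ICTable, root: str) -> float:
    v = ic[term]
    if term == root or v == 0.0 or math.isinf(v):
        return 0.0
    return 1.0 / v


def term_distance_brute(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> float:
    """Exhaustive evaluation of the TopoICSim term distance."""
    if t1 == t2:
        return 0.0
    root = graph.aspect_roots[graph.dag.nodes[t1]["aspect"]]
    dca = disjunctive_brute(graph, t1, t2)
    if dca == {root}:
        return math.inf
    best = math.inf
    for x in dca:
        iic1, len1 = best_side_path(graph, ic, t1, x, root, maximise=False)
        iic2, len2 = best_side_path(graph, ic, t2, x, root, maximise=False)
        wsp = (iic1 + iic2 - _contrib(x, ic, root)) * (len1 + len2)
        liic, llen = best_side_path(graph, ic, x, root, root, maximise=True)
        wlp = liic * llen
        d = math.inf if wlp == 0.0 else wsp / wlp
        best = min(best, d)
    return best


# -- baselines ---------------------------------------------------------

def depth_brute(graph: OntologyGraph, t: str) -> int:
    root = graph.aspect_roots[graph.dag.nodes[t]["aspect"]]
    return max(len(p) - 1 for p in all_paths(graph, t, root))


def lca_brute(graph: OntologyGraph, t1: str, t2: str) -> tuple[str, int, int]:
    """(lca, depth, min through-lca path length), ties lexicographic."""
    com = common_ancestors_brute(graph, t1, t2)
    lca = min(
        com, key=lambda x: (-depth_brute(graph, x), x)
    )
    spl = min(len(p) - 1 for p in all_paths(graph, t1, lca)) + min(
        len(p) - 1 for p in all_paths(graph, t2, lca)
    )
    return lca, depth_brute(graph, lca), spl


def wang_s_brute(
    graph: OntologyGraph, term: str, w_is_a: float = 0.8, w_part_of: float = 0.6
) -> dict[str, float]:
    """S-values as path-product maximisation over enumerated paths."""
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    out = {}
    for x in upward_closure(graph, term):
        best = 0.0
        for p in all_paths(graph, term, x):
            prod = 1.0
            for child, parent in zip(p, p[1:]):
                prod *= weights[graph.dag.edges[child, parent]["relation"]]
            best = max(best, prod)
        out[x] = best
    return out


def min_spl_any_ancestor(graph: OntologyGraph, t1: str, t2: str) -> int:
    """Shortest through-any-common-ancestor path length in edges."""
    return min(
        min(len(p) - 1 for p in all_paths(graph, t1, x))
        + min(len(p) - 1 for p in all_paths(graph, t2, x))
        for x in common_ancestors_brute(graph, t1, t2)
    )


# -- distance correlation ----------------------------------------------

def dcov2_triple_loop(x, y) -> float:
    """Literal triple-loop evaluation of the empirical dcov^2 terms."""
    import numpy as np

    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    n = len(x)

    def d(u, k, l):
        return float(np.linalg.norm(u[k] - u[l]))

    s1 = sum(d(x, k, l) * d(y, k, l) for k in range(n) for l in range(n)) / n**2
    s2 = (
        sum(d(x, k, l) for k in range(n) for l in range(n)) / n**2
        * sum(d(y, k, l) for k in range(n) for l in range(n)) / n**2
    )
    s3 = (
        sum(
            d(x, k, l) * d(y, k, m)
            for k in range(n)
            for l in range(n)
            for m in range(n)
        )
        / n**3
    )
    return s1 + s2 - 2 * s3
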