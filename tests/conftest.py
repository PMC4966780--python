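import math

import pytest

from topoicsim import (
    AnnotationCorpus,
    ICTable,
    build_graph,
    fig2_fixture,
    random_corpus,
    random_ic_table,
    random_rdag,
    RandomCorpusSpec,
    RandomDagSpec,
)


@pytest.fixture(scope="session")
def fig2():
    return fig2_fixture()


@pytest.fixture()
def chain():
    """C -> B -> A, all is_a, root A."""
    return build_graph(
        {"A": "BP", "B": "BP", "C": "BP"},
        [("C", "B", "is_a"), ("B", "A", "is_a")],
    )


@pytest.fixture()
def diamond():
    """D -> {B, C} -> A."""
    return build_graph(
        {"A": "BP", "B": "BP", "C": "BP", "D": "BP"},
        [
            ("D", "B", "is_a"),
            ("D", "C", "is_a"),
            ("B", "A", "is_a"),
            ("C", "A", "is_a"),
        ],
    )


@pytest.fixture()
def diamond_ic():
    def make(ic_b: float, ic_c: float) -> ICTable:
        return ICTable(
            ic={"A": 0.0, "B": ic_b, "C": ic_c, "D": 2.0}, total_genes=10
        )

    return make


def random_case(seed: int, n_lo: int = 4, n_hi: int = 12):
    """A random (graph, ic) pair for oracle tests, pure in the seed."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    graph = random_rdag(RandomDagSpec(n_terms=n, max_parents=3, seed=seed))
    ic = random_ic_table(graph, seed=seed + 1)
    return graph, ic


def random_annotated_case(seed: int, n_terms: int = 10, n_genes: int = 8):
    """(graph, corpus, ic) with IC computed from the corpus."""
    from topoicsim import compute_ic

    graph = random_rdag(RandomDagSpec(n_terms=n_terms, max_parents=3, seed=seed))
    corpus = random_corpus(
        graph, RandomCorpusSpec(n_genes=n_genes, k_min=1, k_max=4, seed=seed + 7)
    )
    ic = compute_ic(corpus, graph)
    return graph, corpus, ic
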