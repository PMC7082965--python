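import networkx as nx
import pytest

from coexnet import (
    ModuleSpec,
    generate_modular_expression,
    pearson_correlation,
    pick_soft_threshold,
    soft_adjacency,
    threshold_edges,
)


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint unit-weight triangles — a textbook modular graph."""
    graph = nx.Graph()
    graph.add_edges_from(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0
    )
    return graph


@pytest.fixture(scope="session")
def planted():
    """Planted 5-module expression design and its thresholded network.

    Five modules of 20 genes at within-module correlation 0.95 over 30
    samples; the soft threshold is auto-selected and edges kept at
    |r| >= 0.7.  Session-scoped because several tests reuse it.
    """
    spec = ModuleSpec(seed=0)
    expr, truth = generate_modular_expression(spec)
    corr = pearson_correlation(expr)
    fit = pick_soft_threshold(corr)
    graph = threshold_edges(corr, soft_adjacency(corr, fit.beta), 0.7)
    return {"expr": expr, "truth": truth, "corr": corr, "fit": fit, "graph": graph}
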