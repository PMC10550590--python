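import numpy as np
import pytest

from pglcn import (
    OmicsCohort,
    PathwayGraph,
    simulate_multiomics_cohort,
    simulate_pathway_graph,
)


@pytest.fixture(scope="session")
def tiny_pathway_graph() -> PathwayGraph:
    """Five pathways in a chain hierarchy with 4-gene disjoint sets."""
    ids = [f"P{i}" for i in range(5)]
    a = np.eye(5, dtype=int)
    for i in range(4):
        a[i, i + 1] = a[i + 1, i] = 1
    gene_sets = {ids[i]: {f"G{4 * i + j}" for j in range(4)} for i in range(5)}
    return PathwayGraph(pathway_ids=ids, adjacency=a, gene_sets=gene_sets)


@pytest.fixture(scope="session")
def small_cohort(tiny_pathway_graph) -> OmicsCohort:
    return simulate_multiomics_cohort(
        40, tiny_pathway_graph, effect_pathways=["P0", "P1"],
        effect_size=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def sim_world():
    """Default synthetic pathway world (30 pathways, 10-effect chain)."""
    graph, effect = simulate_pathway_graph(seed=3)
    return graph, effect
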