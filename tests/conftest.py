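import networkx as nx
import numpy as np
import pytest

from menc import GeneSet, MutationMatrix
from menc.mutation import compute_mutation_scores
from menc.network import MergedGraph, Role, extract_semilocal


@pytest.fixture
def tiny_matrix():
    """3 genes x 3 patients; patient burdens N = (2, 2, 0)."""
    return MutationMatrix(
        genes=["g1", "g2", "g3"],
        patients=["p1", "p2", "p3"],
        values=np.array([[1, 1, 0], [0, 1, 0], [1, 0, 0]]),
    )


def random_attributed_graph(rng, max_nodes=15, n_patients=6):
    """Random graph + roles + consistent mutation matrix, for oracle checks.

    Returns (merged_graph, score_table, matrix, source) where source is a
    mutated node; nodes with role MUTATED/BOTH are guaranteed at least one
    mutation in the matrix.
    """
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.6))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    roles = {}
    for node in g.nodes:
        roles[node] = [Role.MUTATED, Role.DEG, Role.BOTH][int(rng.integers(3))]
    mutated = [x for x, r in roles.items() if r in (Role.MUTATED, Role.BOTH)]
    if not mutated:
        node = sorted(g.nodes)[0]
        roles[node] = Role.MUTATED
        mutated = [node]
    genes = sorted(g.nodes)
    values = (rng.random((len(genes), n_patients)) < 0.35).astype(np.int8)
    gidx = {x: i for i, x in enumerate(genes)}
    for x in mutated:
        if values[gidx[x]].sum() == 0:
            values[gidx[x], int(rng.integers(n_patients))] = 1
    m = MutationMatrix(genes, [f"p{j}" for j in range(n_patients)], values)
    scores = compute_mutation_scores(m)
    merged = MergedGraph(graph=g, role=roles)
    source = mutated[int(rng.integers(len(mutated)))]
    return merged, scores, m, source


@pytest.fixture
def make_semilocal():
    """Build a SemiLocalNetwork directly from explicit edges and roles."""
    def _make(source, edges, roles):
        g = nx.Graph()
        g.add_nodes_from(roles)
        g.add_edges_from(edges)
        merged = MergedGraph(graph=g, role=dict(roles))
        return extract_semilocal(merged, source)
    return _make


@pytest.fixture
def gene_set():
    def _make(*members, name="set"):
        return GeneSet(name, members)
    return _make
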