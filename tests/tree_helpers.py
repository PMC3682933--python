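"""Shared test helper: additive distance matrices from random binary trees."""

import networkx as nx
import numpy as np

import snpanel as sp


def random_additive_matrix(n_leaves, rng):
    """Distance matrix of a random binary tree with positive branch lengths."""
    g = nx.Graph()
    nodes = [f"L{i}" for i in range(n_leaves)]
    g.add_nodes_from(nodes)
    internal = 0
    pool = list(nodes)
    while len(pool) > 1:
        a = pool.pop(int(rng.integers(len(pool))))
        b = pool.pop(int(rng.integers(len(pool))))
        u = f"I{internal}"
        internal += 1
        g.add_edge(a, u, length=float(rng.uniform(0.5, 3.0)))
        g.add_edge(b, u, length=float(rng.uniform(0.5, 3.0)))
        pool.append(u)
    values = np.zeros((n_leaves, n_leaves))
    for i, leaf in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(g, leaf, weight="length")
        for j, other in enumerate(nodes):
            values[i, j] = lengths[other]
    np.fill_diagonal(values, 0.0)
    return sp.DistanceMatrix(nodes, (values + values.T) / 2)
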