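"""Information-retention checks for panels: NJ trees, Mantel test, MSN.

The neighbour-joining tree (Saitou & Nei agglomeration) supplies patristic
distances — path lengths between leaves — on which the Mantel test compares
the distance structure of the full barcode against that of a concatenated
SNP panel.  The Mantel statistic is the Spearman correlation of the two
off-diagonal vectors; the null distribution comes from simultaneous
row/column permutations of one matrix.

The minimum spanning network over haplotype Hamming distances contains every
edge that belongs to at least one minimum spanning tree; haplotypes shared
between described species stand out as multi-species nodes and are the
signature of mitochondrial introgression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .distances import DistanceMatrix, hamming_matrix


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Neighbour-joining
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """An unrooted tree stored as a weighted graph, rooted only for output."""

    graph: nx.Graph
    leaves: list[str]
    root: str

    def patristic_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances."""
        values = np.zeros((len(self.leaves), len(self.leaves)))
        for i, leaf in enumerate(self.leaves):
            lengths = nx.single_source_dijkstra_path_length(self.graph, leaf, weight="length")
            for j, other in enumerate(self.leaves):
                values[i, j] = lengths[other]
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(list(self.leaves), values)

    def newick(self) -> str:
        def fmt(node: str, parent: str | None) -> str:
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return node
            inner = ",".join(
                f"{fmt(c, node)}:{self.graph[node][c]['length']:.8f}" for c in children
            )
            return f"({inner})"

        return fmt(self.root, None) + ";"


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbour-joining tree (Saitou-Nei) from a distance matrix.

    Negative branch lengths are clamped to zero with the deficit shifted to
    the sister branch, preserving the joined pair's mutual distance.
    """
    if dm.n < 3:
        raise EvaluationError("need at least 3 labels for NJ")
    if not np.isfinite(dm.values).all():
        raise EvaluationError("distances must be finite")
    g = nx.Graph()
    active = list(range(dm.n))
    names = {i: dm.labels[i] for i in active}
    D = {(i, j): float(dm.values[i, j]) for i in active for j in active if i < j}

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    next_id = dm.n
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        best_q = np.inf
        for i, j in combinations(active, 2):
            q = (m - 2) * d(i, j) - r[i] - r[j]
            if q < best_q - 1e-15:
                best_q, best = q, (i, j)
        i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:  # shift the deficit to the sister branch
            li, lj = 0.0, lj + li
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)  # non-additive input: both negative
        u = next_id
        next_id += 1
        names[u] = f"_nj{u}"
        g.add_edge(names[i], names[u], length=li)
        g.add_edge(names[j], names[u], length=lj)
        for k in active:
            if k in (i, j):
                continue
            D[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]
    a, b = active
    g.add_edge(names[a], names[b], length=max(d(a, b), 0.0))
    root = names[active[-1]]
    return Tree(graph=g, leaves=list(dm.labels), root=root)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_two_tailed: float
    n_permutations: int


def mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    n_permutations: int = 10_000,
    seed: int = 1,
) -> MantelResult:
    """Mantel test with Spearman correlation over off-diagonal entries.

    The null distribution permutes the labels (rows and columns
    simultaneously) of the second matrix; the two-tailed p-value is
    ``(count(|r_perm| >= |r_obs|) + 1) / (n_permutations + 1)``.
    """
    if dmA.labels != dmB.labels:
        raise EvaluationError("matrices must share the same labels in the same order")
    n = dmA.n
    iu = np.triu_indices(n, k=1)
    xa = rankdata(dmA.values[iu])
    xb = rankdata(dmB.values[iu])
    # square matrix of B's off-diagonal ranks, so permuting labels permutes ranks
    rank_sq = np.zeros((n, n))
    rank_sq[iu] = xb
    rank_sq = rank_sq + rank_sq.T

    def pearson(y: np.ndarray) -> float:
        xc = xa - xa.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        if denom == 0:
            return 0.0
        return float((xc * yc).sum() / denom)

    r_obs = pearson(xb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y = rank_sq[np.ix_(perm, perm)][iu]
        if abs(pearson(y)) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p_two_tailed=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Minimum spanning haplotype network
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNode:
    hap_id: str
    sequence: str
    member_ids: list[str]
    species: list[str]  # unique species labels among members
    multiplicity: int


@dataclass
class HaplotypeNetwork:
    nodes: list[HaplotypeNode]
    edges: list[tuple[str, str, int, bool]]  # (hapA, hapB, weight, in_msn)

    def msn_edges(self) -> list[tuple[str, str, int]]:
        return [(a, b, w) for a, b, w, in_msn in self.edges if in_msn]

    def msn_total_weight(self) -> int:
        """Total weight of one minimum spanning tree contained in the MSN."""
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.hap_id)
        for a, b, w in self.msn_edges():
            g.add_edge(a, b, weight=w)
        mst = nx.minimum_spanning_tree(g)
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def min_spanning_network(
    sequences: list[str],
    species_labels: list[str],
    ids: list[str] | None = None,
) -> HaplotypeNetwork:
    """Haplotype network containing every edge of every minimum spanning tree.

    Identical sequences collapse into one haplotype node.  By the Kruskal
    equal-weight closure, an edge (u, v, w) belongs to some MST iff u and v
    lie in different connected components once all edges of weight < w are
    present; those edges form the MSN.
    """
    if len(sequences) < 2:
        raise EvaluationError("need at least 2 sequences")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(sequences))]
    order: dict[str, int] = {}
    nodes: list[HaplotypeNode] = []
    for sid, sp, seq in zip(ids, species_labels, sequences):
        if seq not in order:
            order[seq] = len(nodes)
            nodes.append(HaplotypeNode(
                hap_id=f"H{len(nodes) + 1}", sequence=seq,
                member_ids=[], species=[], multiplicity=0,
            ))
        node = nodes[order[seq]]
        node.member_ids.append(sid)
        if sp not in node.species:
            node.species.append(sp)
        node.multiplicity += 1
    if len(nodes) == 1:
        return HaplotypeNetwork(nodes=nodes, edges=[])
    dm = hamming_matrix([n.sequence for n in nodes], [n.hap_id for n in nodes])
    weights = dm.values.astype(int)
    h = len(nodes)
    all_edges = sorted(
        ((int(weights[i, j]), i, j) for i in range(h) for j in range(i + 1, h)),
        key=lambda e: e[0],
    )
    parent = list(range(h))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    in_msn: dict[tuple[int, int], bool] = {}
    pos = 0
    while pos < len(all_edges):
        w = all_edges[pos][0]
        tier = []
        while pos < len(all_edges) and all_edges[pos][0] == w:
            tier.append(all_edges[pos])
            pos += 1
        # membership judged against components formed by strictly lighter edges
        for _, i, j in tier:
            in_msn[(i, j)] = find(i) != find(j)
        for _, i, j in tier:
            if in_msn[(i, j)]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    edges = [
        (nodes[i].hap_id, nodes[j].hap_id, int(weights[i, j]), in_msn[(i, j)])
        for _, i, j in all_edges
    ]
    return HaplotypeNetwork(nodes=nodes, edges=edges)


def shared_haplotypes(net: HaplotypeNetwork) -> list[dict]:
    """Nodes whose members span two or more described species."""
    return [
        {
            "hap_id": node.hap_id,
            "species": list(node.species),
            "member_ids": list(node.member_ids),
            "multiplicity": node.multiplicity,
        }
        for node in net.nodes
        if len(node.species) >= 2
    ]
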