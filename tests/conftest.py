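"""Shared fixtures and independent oracles for the test suite.

Oracles deliberately avoid the code paths they check: shortest paths come
from scipy's sparse csgraph, tree distances and topology comparisons from
dendropy, and Jaccard/degree recounts from plain set arithmetic.
"""

from __future__ import annotations

import random

import dendropy
import networkx as nx
import numpy as np
import pytest

from netsketch import synthetic_data as sd


@pytest.fixture(scope="session")
def bat_network():
    return sd.gen_bat_fixture(sd.DEFAULT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bfs_distances_scipy(graph: nx.Graph, source) -> dict:
    """Unit-weight shortest-path distances via scipy csgraph (not networkx)."""
    from scipy.sparse.csgraph import dijkstra

    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    mat = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csr")
    dist = dijkstra(mat, directed=False, unweighted=True, indices=index[source])
    return {n: int(d) for n, d in zip(nodes, dist) if np.isfinite(d)}


def random_binary_newick(labels: list[str], seed: int, lo=0.05, hi=0.3) -> str:
    """Random binary tree over the labels with uniform branch lengths,
    written as newick; built by random sequential pair joining."""
    rnd = random.Random(seed)

    def bl() -> str:
        return f":{rnd.uniform(lo, hi):.6f}"

    parts = [lab + bl() for lab in labels]
    while len(parts) > 2:
        i, j = sorted(rnd.sample(range(len(parts)), 2), reverse=True)
        a, b = parts.pop(i), parts.pop(j)
        parts.append(f"({a},{b})" + bl())
    return "(" + ",".join(parts) + ");"


def newick_leaf_distances(newick: str) -> dict[frozenset, float]:
    """Pairwise leaf path lengths of a newick tree, via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in pdm.taxon_iter():
        for t2 in pdm.taxon_iter():
            if t1 is not t2:
                out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


def newick_bipartitions(newick: str) -> set[frozenset]:
    """Nontrivial splits of an (unrooted) newick tree, via dendropy; each
    split is reported as the side not containing the smallest leaf label."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.encode_bipartitions()
    labels = sorted(t.label for t in tree.taxon_namespace)
    anchor = labels[0]
    out = set()
    for bip in tree.bipartition_encoding:
        side = frozenset(t.label for t in bip.leafset_taxa(tree.taxon_namespace))
        if anchor in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def additive_matrix_from_newick(newick: str):
    """Label-ordered DistanceMatrix of a tree's path distances (dendropy)."""
    from netsketch.sketch_phylo import DistanceMatrix

    dist = newick_leaf_distances(newick)
    labels = sorted({lab for pair in dist for lab in pair})
    vals = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                vals[i, j] = dist[frozenset((a, b))]
    return DistanceMatrix(labels, vals)
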