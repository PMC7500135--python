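"""Distance-based tree building: neighbor joining, balanced-minimum-evolution
NNI refinement, and quartet-based (REQ) branch supports.

Trees are unrooted, stored as an undirected graph whose leaf nodes carry
genome labels and whose edges carry branch lengths (substitutions per site).
Internal-branch confidence is the rate of elementary quartets: the fraction
of leaf quartets straddling the branch whose distance-based resolution
(four-point condition, strict inequality) agrees with the branch's
bipartition.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .sketch import DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_QUARTETS = 10_000


class Tree:
    """Unrooted phylogeny with branch lengths and optional branch supports."""

    def __init__(self) -> None:
        self.g = nx.Graph()
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def add_leaf(self, label: str) -> int:
        node = self._next_id
        self._next_id += 1
        self.g.add_node(node, label=label)
        return node

    def add_internal(self) -> int:
        node = self._next_id
        self._next_id += 1
        self.g.add_node(node)
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.g.add_edge(u, v, length=float(length))

    def copy(self) -> "Tree":
        t = Tree.__new__(Tree)
        t.g = self.g.copy()
        t._next_id = self._next_id
        return t

    # -- queries ----------------------------------------------------------
    def is_leaf(self, node: int) -> bool:
        return "label" in self.g.nodes[node]

    def leaf_nodes(self) -> list[int]:
        return [n for n in self.g.nodes if self.is_leaf(n)]

    def leaves(self) -> list[str]:
        return sorted(self.g.nodes[n]["label"] for n in self.leaf_nodes())

    def branch_length(self, u: int, v: int) -> float:
        return self.g.edges[u, v]["length"]

    def internal_edges(self) -> list[tuple[int, int]]:
        """Edges whose endpoints are both internal; each defines a nontrivial
        bipartition of the leaf set."""
        return [
            (u, v)
            for u, v in self.g.edges
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def bipartition(self, u: int, v: int) -> tuple[frozenset, frozenset]:
        """Leaf labels on the u side and v side of edge (u, v)."""
        side_u = self._side_labels(u, v)
        side_v = frozenset(self.leaves()) - side_u
        return side_u, side_v

    def _side_labels(self, start: int, blocked: int) -> frozenset:
        seen = {start}
        stack = [start]
        labels = []
        while stack:
            node = stack.pop()
            if self.is_leaf(node):
                labels.append(self.g.nodes[node]["label"])
            for nb in self.g.neighbors(node):
                if nb not in seen and not (node == start and nb == blocked):
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(labels)

    def bipartitions(self) -> set[frozenset]:
        """Canonical set of nontrivial splits (the side not containing the
        lexicographically smallest leaf), for topology comparison."""
        anchor = min(self.leaves())
        out = set()
        for u, v in self.internal_edges():
            a, b = self.bipartition(u, v)
            out.add(b if anchor in a else a)
        return out

    def supports(self) -> dict[frozenset, float]:
        anchor = min(self.leaves())
        out = {}
        for u, v in self.internal_edges():
            if "support" in self.g.edges[u, v]:
                a, b = self.bipartition(u, v)
                out[b if anchor in a else a] = self.g.edges[u, v]["support"]
        return out

    def leaf_distances(self) -> dict[frozenset, float]:
        """Path-length (sum of branch lengths) between every leaf pair."""
        out = {}
        for a in self.leaf_nodes():
            dist = nx.single_source_dijkstra_path_length(self.g, a, weight="length")
            for b in self.leaf_nodes():
                if a != b:
                    key = frozenset(
                        (self.g.nodes[a]["label"], self.g.nodes[b]["label"])
                    )
                    out[key] = dist[b]
        return out

    # -- output -----------------------------------------------------------
    def to_newick(self, length_decimals: int = 6, support_decimals: int = 2) -> str:
        internal = [n for n in self.g.nodes if not self.is_leaf(n)]
        root = internal[0] if internal else next(iter(self.g.nodes))

        def render(node: int, parent: int | None) -> str:
            if self.is_leaf(node):
                s = self.g.nodes[node]["label"]
            else:
                children = [nb for nb in self.g.neighbors(node) if nb != parent]
                s = "(" + ",".join(render(c, node) for c in children) + ")"
                if parent is not None and "support" in self.g.edges[node, parent]:
                    s += f"{self.g.edges[node, parent]['support']:.{support_decimals}f}"
            if parent is not None:
                s += f":{self.g.edges[node, parent]['length']:.{length_decimals}f}"
            return s

        return render(root, None) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Neighbor joining with the standard Q-criterion.

    Deterministic: Q ties are broken by the lexicographically smallest pair
    of cluster keys (the minimum leaf label in each cluster).  Negative
    branch lengths are clamped to 0 with a logged count.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    tree = Tree()
    nodes = [tree.add_leaf(lab) for lab in matrix.labels]
    keys = {node: lab for node, lab in zip(nodes, matrix.labels)}
    D: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        D[frozenset((nodes[i], nodes[j]))] = float(matrix.values[i, j])

    active = list(nodes)
    n_clamped = 0

    def d(a: int, b: int) -> float:
        return D[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        R = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * d(a, b) - R[a] - R[b]
            tie = tuple(sorted((keys[a], keys[b])))
            if best is None or (q, tie) < (best[0], best[1]):
                best = (q, tie, a, b)
        _, _, i, j = best
        li = 0.5 * d(i, j) + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            li, n_clamped = 0.0, n_clamped + 1
        if lj < 0:
            lj, n_clamped = 0.0, n_clamped + 1
        u = tree.add_internal()
        tree.add_edge(u, i, li)
        tree.add_edge(u, j, lj)
        for k in active:
            if k in (i, j):
                continue
            D[frozenset((u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        keys[u] = min(keys[i], keys[j])
        active = [a for a in active if a not in (i, j)] + [u]

    i, j, k = sorted(active, key=lambda a: keys[a])
    c = tree.add_internal()
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        lx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
        if lx < 0:
            lx, n_clamped = 0.0, n_clamped + 1
        tree.add_edge(c, x, lx)
    if n_clamped:
        logger.warning("clamped %d negative branch lengths to 0", n_clamped)
    return tree


def _pair_weights(tree: Tree) -> dict[frozenset, float]:
    """Balanced (Pauplin) weight per leaf pair: the product over internal
    nodes on the connecting path of 1/(degree - 1); equals
    2^(-number of internal path nodes) on fully binary trees."""
    weights: dict[frozenset, float] = {}
    for a in tree.leaf_nodes():
        stack: list[tuple[int, int | None, float]] = [(a, None, 1.0)]
        while stack:
            node, parent, w = stack.pop()
            for nb in tree.g.neighbors(node):
                if nb == parent:
                    continue
                if tree.is_leaf(nb):
                    weights[frozenset((a, nb))] = w
                else:
                    stack.append((nb, node, w / (tree.g.degree(nb) - 1)))
    return weights


def pauplin_length(tree: Tree, matrix: DistanceMatrix) -> float:
    """Balanced tree length: sum of Pauplin-weighted pairwise distances."""
    if sorted(tree.leaves()) != sorted(matrix.labels):
        raise ValueError("tree leaves do not match matrix labels")
    node_label = {n: tree.g.nodes[n]["label"] for n in tree.leaf_nodes()}
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    total = 0.0
    for pair, w in _pair_weights(tree).items():
        a, b = tuple(pair)
        total += w * matrix.values[idx[node_label[a]], idx[node_label[b]]]
    return total


def _nni_neighbors(tree: Tree, u: int, v: int) -> Iterator[tuple[int, int]]:
    """The two nearest-neighbor-interchange moves across internal edge (u, v)
    of a binary tree, as (subtree-root at u side, subtree-root at v side)."""
    us = [nb for nb in tree.g.neighbors(u) if nb != v]
    vs = [nb for nb in tree.g.neighbors(v) if nb != u]
    if len(us) != 2 or len(vs) != 2:
        return
    b = us[1]
    for c in vs:
        yield b, c


def _apply_nni(tree: Tree, u: int, v: int, b: int, c: int) -> None:
    lb = tree.branch_length(u, b)
    lc = tree.branch_length(v, c)
    tree.g.remove_edge(u, b)
    tree.g.remove_edge(v, c)
    tree.add_edge(u, c, lc)
    tree.add_edge(v, b, lb)


def bme_refine(tree: Tree, matrix: DistanceMatrix, max_rounds: int = 50) -> Tree:
    """Greedy NNI hill climb minimizing the balanced tree length.

    Applies the single best strictly-improving interchange per round until
    no move improves or ``max_rounds`` is reached.  Branch lengths travel
    with their subtrees and are not re-estimated; the balanced length of the
    output never exceeds that of the input.
    """
    current = tree.copy()
    cur_len = pauplin_length(current, matrix)
    for _ in range(max_rounds):
        best_move = None
        best_len = cur_len
        for u, v in current.internal_edges():
            for b, c in _nni_neighbors(current, u, v):
                cand = current.copy()
                _apply_nni(cand, u, v, b, c)
                cand_len = pauplin_length(cand, matrix)
                if cand_len < best_len - 1e-12:
                    best_len = cand_len
                    best_move = (u, v, b, c)
        if best_move is None:
            break
        _apply_nni(current, *best_move)
        cur_len = best_len
    return current


def _edge_rng(seed: int, side_a: frozenset, side_b: frozenset) -> np.random.Generator:
    # sub-seed derived from the bipartition itself so sampled supports are
    # invariant under leaf/label permutations and edge iteration order
    token = "|".join(sorted(side_a)) + "||" + "|".join(sorted(side_b))
    return np.random.default_rng([seed & 0xFFFFFFFF, zlib.crc32(token.encode())])


def req_support(
    tree: Tree,
    matrix: DistanceMatrix,
    max_quartets: int = DEFAULT_MAX_QUARTETS,
    seed: int = 0,
) -> Tree:
    """Annotate each internal branch with its rate of elementary quartets.

    For a branch splitting the leaves into A | B, a quartet {a1, a2, b1, b2}
    supports the branch when d(a1,a2) + d(b1,b2) is strictly smaller than
    both cross sums (ties count as non-supporting).  All quartets are
    enumerated when their number is at most ``max_quartets``; otherwise
    ``max_quartets`` quartets are sampled uniformly with the given seed.
    """
    if sorted(tree.leaves()) != sorted(matrix.labels):
        raise ValueError("tree leaves do not match matrix labels")
    out = tree.copy()
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    vals = matrix.values

    def quartet_supports(a1, a2, b1, b2) -> bool:
        within = vals[idx[a1], idx[a2]] + vals[idx[b1], idx[b2]]
        cross = min(
            vals[idx[a1], idx[b1]] + vals[idx[a2], idx[b2]],
            vals[idx[a1], idx[b2]] + vals[idx[a2], idx[b1]],
        )
        return within < cross

    for u, v in out.internal_edges():
        side_a, side_b = out.bipartition(u, v)
        a_sorted, b_sorted = sorted(side_a), sorted(side_b)
        n_total = (
            len(a_sorted) * (len(a_sorted) - 1) // 2
            * len(b_sorted) * (len(b_sorted) - 1) // 2
        )
        if n_total == 0:
            continue
        if n_total <= max_quartets:
            n_support = sum(
                quartet_supports(a1, a2, b1, b2)
                for a1, a2 in itertools.combinations(a_sorted, 2)
                for b1, b2 in itertools.combinations(b_sorted, 2)
            )
            support = n_support / n_total
        else:
            rng = _edge_rng(seed, side_a, side_b)
            n_support = 0
            for _ in range(max_quartets):
                ia = rng.choice(len(a_sorted), size=2, replace=False)
                ib = rng.choice(len(b_sorted), size=2, replace=False)
                n_support += quartet_supports(
                    a_sorted[ia[0]], a_sorted[ia[1]], b_sorted[ib[0]], b_sorted[ib[1]]
                )
            support = n_support / max_quartets
        out.g.edges[u, v]["support"] = support
    return out


def build_tree(
    matrix: DistanceMatrix,
    max_rounds: int = 50,
    max_quartets: int = DEFAULT_MAX_QUARTETS,
    seed: int = 0,
) -> Tree:
    """NJ construction, BME refinement, then REQ branch supports."""
    return req_support(
        bme_refine(nj_tree(matrix), matrix, max_rounds=max_rounds),
        matrix,
        max_quartets=max_quartets,
        seed=seed,
    )
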