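"""Seeded generators for every test input: random and structured networks
(including the degree-constrained 78-node/216-edge hub fixture) and genome
sets evolved along a known guide tree by exact-proportion point substitution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np

from .net_io import Network, read_edgelist

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42

#: Reference hub degree table as advertised for the 78-node/216-edge network.
#: NOTE: this table is not realizable by a simple graph — see
#: :func:`hub_degree_sum_bound` — and is kept for reporting and rank order.
PRINTED_HUB_DEGREES: dict[str, int] = {
    "BatD": 55,
    "Hypo": 53,
    "BatE": 39,
    "BatB": 30,
    "BatA": 29,
    "BatC": 23,
    "MoxR": 22,
    "PA3071": 21,
}

#: Hub degrees actually realized by the packaged fixture: same labels, same
#: rank order and the same maximum (55), with the lower seven degrees shaved
#: proportionally so the table becomes graphical at 216 edges (sum 240 <= 244,
#: the hard bound).
BAT_HUB_DEGREES: dict[str, int] = {
    "BatD": 55,
    "Hypo": 45,
    "BatE": 33,
    "BatB": 26,
    "BatA": 25,
    "BatC": 20,
    "MoxR": 19,
    "PA3071": 17,
}
BAT_N_NODES = 78
BAT_N_EDGES = 216
_BAT_NONHUB_MAX_DEGREE = 8  # keeps hubs strictly the top eight; helps feasibility


def hub_degree_sum_bound(n_hubs: int, n_edges: int) -> int:
    """Maximum possible degree sum of ``n_hubs`` designated nodes in any
    simple graph with ``n_edges`` edges.

    Counting: sum(deg hubs) = 2*e(H,H) + e(H,O) = e(H,H) + (e(H,H) + e(H,O))
    <= C(n_hubs, 2) + n_edges.  The advertised table sums to 272 while the
    bound at 8 hubs and 216 edges is 244, so that table is unrealizable; the
    packaged fixture keeps the node/edge counts, the hub rank order and the
    maximum degree, and relaxes the lower seven degrees (sum 240).
    """
    return n_hubs * (n_hubs - 1) // 2 + n_edges


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative network generator request.

    ``model`` is one of ``erdos_renyi`` (params n, p), ``barabasi_albert``
    (n, m), ``configuration`` (degree_sequence), ``bary_tree`` (b, depth) or
    ``bat_fixture`` (no params).
    """

    model: str
    params: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED


@dataclass(frozen=True)
class GenomeSimSpec:
    """Genome-evolution request: a newick guide tree whose branch lengths are
    per-branch substitution proportions, a sequence length, and a seed."""

    tree: str
    length: int
    seed: int = DEFAULT_SEED


def gen_network(spec: NetworkSpec) -> Network:
    """Generate a simple undirected graph; deterministic for a fixed seed."""
    model, p = spec.model, dict(spec.params)
    if model == "erdos_renyi":
        return nx.gnp_random_graph(int(p["n"]), float(p["p"]), seed=spec.seed)
    if model == "barabasi_albert":
        return nx.barabasi_albert_graph(int(p["n"]), int(p["m"]), seed=spec.seed)
    if model == "bary_tree":
        return nx.balanced_tree(int(p["b"]), int(p["depth"]))
    if model == "configuration":
        return _configuration_graph(
            [int(d) for d in p["degree_sequence"]],
            np.random.default_rng(spec.seed),
        )
    if model == "bat_fixture":
        return gen_bat_fixture(spec.seed)
    raise ValueError(f"unknown network model {spec.model!r}")


def _configuration_graph(
    degree_sequence: list[int],
    rng: np.random.Generator,
    max_attempts: int = 5000,
) -> Network:
    """Stub-matching configuration model; whole matchings producing a
    self-loop or parallel edge are rejected and redrawn."""
    n = len(degree_sequence)
    if n == 0 or any(d < 0 for d in degree_sequence):
        raise ValueError("degree sequence must be non-empty and non-negative")
    if sum(degree_sequence) % 2 != 0:
        raise ValueError("infeasible degree sequence: odd degree sum")
    if max(degree_sequence) >= n:
        raise ValueError("infeasible degree sequence: max degree >= n")
    stubs = np.repeat(np.arange(n), degree_sequence)
    for _ in range(max_attempts):
        rng.shuffle(stubs)
        pairs = stubs.reshape(-1, 2)
        if (pairs[:, 0] == pairs[:, 1]).any():
            continue
        edges = {frozenset(map(int, e)) for e in pairs}
        if len(edges) < len(pairs):
            continue
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(tuple(e) for e in edges)
        return g
    raise RuntimeError(
        "configuration-model rejection budget exhausted; try a different seed"
    )


def gen_bat_fixture(seed: int = DEFAULT_SEED) -> Network:
    """Generate the degree-constrained hub fixture network.

    Exactly 78 nodes and 216 edges; the eight designated hubs carry the
    degrees of :data:`BAT_HUB_DEGREES` (maximum 55, in the advertised rank
    order); the residual degree stubs are spread over the remaining 70 nodes
    (each degree >= 1) from a truncated geometric draw repaired to the exact
    total.  The graphical sequence is realised
    deterministically (Havel-Hakimi) and mixed by degree-preserving edge
    swaps.  Raises if the constraints cannot be met within the retry budget;
    constraints are never silently relaxed.
    """
    hub_degrees = list(BAT_HUB_DEGREES.values())
    residual = 2 * BAT_N_EDGES - sum(hub_degrees)
    n_other = BAT_N_NODES - len(hub_degrees)
    master = np.random.default_rng(seed)
    for _ in range(50):
        rng = np.random.default_rng(master.integers(2**63))
        other = _residual_degrees(rng, n_other, residual)
        sequence = hub_degrees + other
        if not nx.is_graphical(sequence):
            continue
        g = nx.havel_hakimi_graph(sequence)
        try:
            nx.double_edge_swap(
                g, nswap=4 * BAT_N_EDGES, max_tries=200 * BAT_N_EDGES,
                seed=int(rng.integers(2**32)),
            )
        except nx.NetworkXError:
            continue
        g = _relabel_bat(g)
        if _bat_constraints_ok(g):
            return g
    raise RuntimeError("could not satisfy the fixture constraints; retry budget spent")


def _residual_degrees(rng: np.random.Generator, n: int, total: int) -> list[int]:
    """Heavy-tailed non-hub degrees: truncated geometric, repaired to sum to
    ``total`` while staying within [1, cap]."""
    cap = _BAT_NONHUB_MAX_DEGREE
    degrees = np.clip(rng.geometric(0.36, size=n), 1, cap)
    while degrees.sum() > total:
        candidates = np.flatnonzero(degrees > 1)
        degrees[rng.choice(candidates)] -= 1
    while degrees.sum() < total:
        candidates = np.flatnonzero(degrees < cap)
        degrees[rng.choice(candidates)] += 1
    return [int(d) for d in degrees]


def _relabel_bat(g: Network) -> Network:
    by_degree: dict[int, list] = {}
    for node, deg in g.degree():
        by_degree.setdefault(deg, []).append(node)
    mapping: dict = {}
    for label, deg in BAT_HUB_DEGREES.items():
        nodes = by_degree.get(deg, [])
        if len(nodes) != 1:
            return nx.relabel_nodes(g, {n: f"X{n}" for n in g})  # fails the check
        mapping[nodes[0]] = label
    rest = sorted(n for n in g.nodes if n not in mapping)
    for i, node in enumerate(rest, start=1):
        mapping[node] = f"P{i:02d}"
    return nx.relabel_nodes(g, mapping)


def _bat_constraints_ok(g: Network) -> bool:
    if g.number_of_nodes() != BAT_N_NODES or g.number_of_edges() != BAT_N_EDGES:
        return False
    if any(g.degree(n) == 0 for n in g.nodes):
        return False
    return all(
        label in g and g.degree(label) == deg for label, deg in BAT_HUB_DEGREES.items()
    )


def load_bat_fixture() -> Network:
    """Load the frozen packaged copy of the fixture network (identical to
    ``gen_bat_fixture(DEFAULT_SEED)``)."""
    ref = resources.files("netsketch").joinpath("data/bat_fixture.tsv")
    with resources.as_file(ref) as path:
        return read_edgelist(path)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def star_newick(labels: list[str], p: float) -> str:
    """Newick for a star tree with the same substitution proportion on every
    terminal branch."""
    return "(" + ",".join(f"{lab}:{p}" for lab in labels) + ");"


def simulate_genomes(spec: GenomeSimSpec) -> dict[str, str]:
    """Evolve genomes along the guide tree by exact-proportion substitution.

    The root sequence is uniform over A/C/G/T.  Along each branch of
    proportion p, exactly ``round(p * length)`` positions (chosen without
    replacement) are substituted to a uniformly random *different* base, so
    parent-child Hamming proportions are exact by construction.  Inner nodes
    without labels are transient; the returned mapping covers leaf labels
    (and any labelled internal nodes, e.g. an explicitly named root).
    """
    if spec.length < 1:
        raise ValueError("sequence length must be >= 1")
    guide = dendropy.Tree.get(
        data=spec.tree, schema="newick", preserve_underscores=True
    )
    for edge in guide.preorder_edge_iter():
        p = edge.length or 0.0
        if not 0.0 <= p < 0.75:
            raise ValueError(f"substitution proportion {p} outside [0, 0.75)")
    rng = np.random.default_rng(spec.seed)
    root_seq = rng.choice(4, size=spec.length).astype(np.uint8)

    out: dict[str, str] = {}
    emitted: list[str] = []

    def name_of(node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def walk(node, seq: np.ndarray) -> None:
        name = name_of(node)
        if node.is_leaf():
            if not name:
                raise ValueError("unlabelled leaf in guide tree")
            out[name] = _decode(seq)
            emitted.append(name)
        elif name:
            out[name] = _decode(seq)
            emitted.append(name)
        for child in node.child_nodes():
            walk(child, _mutate(seq, child.edge.length or 0.0, rng))

    walk(guide.seed_node, root_seq)
    if len(emitted) != len(set(emitted)):
        raise ValueError("duplicate labels in guide tree")
    return out


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    m = int(round(p * len(seq)))
    if m == 0:
        return seq.copy()
    child = seq.copy()
    positions = rng.choice(len(seq), size=m, replace=False)
    offsets = rng.integers(1, 4, size=m).astype(np.uint8)
    child[positions] = (child[positions] + offsets) % 4
    return child


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write all genomes into one multi-FASTA file."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=label, description="")
        for label, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def write_fasta_dir(sequences: dict[str, str], directory: str | Path) -> list[Path]:
    """Write one FASTA file per genome (file stem = genome label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, seq in sequences.items():
        path = directory / f"{label}.fasta"
        write_fasta({label: seq}, path)
        paths.append(path)
    return paths
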