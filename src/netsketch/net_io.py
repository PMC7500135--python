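"""Interaction-table input, confidence filtering and seed-network construction.

Interaction tables follow the STRING ``protein.links`` flat-file dialect:
whitespace-separated columns ``protein_a protein_b combined_score``, with an
optional header line starting with ``protein1`` or ``#``.  Combined scores are
stored either on the native 0-1000 integer scale or already normalised to
[0, 1]; the reader auto-detects the dialect (any score > 1 implies 0-1000)
unless an explicit scale is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: A network is a simple undirected graph; edge weights are not retained
#: after confidence filtering.
Network = nx.Graph


@dataclass(frozen=True)
class Interaction:
    """A confidence-scored undirected protein-protein interaction."""

    protein_a: str
    protein_b: str
    score: float

    def pair(self) -> frozenset:
        return frozenset((self.protein_a, self.protein_b))


@dataclass(frozen=True)
class MappingRow:
    query: str
    reference: str
    identity: float
    coverage: float


def _is_header(fields: Sequence[str]) -> bool:
    return fields[0].startswith("#") or fields[0].lower().startswith("protein1")


def read_interactions(
    path: str | Path,
    score_threshold: float = 0.4,
    scale: str = "auto",
) -> list[Interaction]:
    """Read a STRING-style links table and keep interactions at or above
    ``score_threshold`` (on the normalised 0-1 scale).

    Parameters
    ----------
    path:
        Whitespace-separated table with at least three columns.
    score_threshold:
        Minimum normalised confidence, inclusive; must lie in [0, 1].
    scale:
        ``"auto"`` (any raw score > 1 implies the 0-1000 dialect),
        ``"fractional"`` (scores already in [0, 1]) or ``"string1000"``
        (always divide by 1000).

    Self-interactions are dropped (with a logged count) so that the returned
    rows satisfy ``protein_a != protein_b``.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    if scale not in ("auto", "fractional", "string1000"):
        raise ValueError(f"unknown scale {scale!r}")
    path = Path(path)

    rows: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and _is_header(fields):
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed score {fields[2]!r}"
                ) from exc
            rows.append((fields[0], fields[1], score))

    if scale == "auto":
        scale = "string1000" if any(s > 1.0 for _, _, s in rows) else "fractional"
    divisor = 1000.0 if scale == "string1000" else 1.0

    kept: list[Interaction] = []
    n_self = 0
    for a, b, raw in rows:
        score = raw / divisor
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"normalised score {score} for ({a}, {b}) outside [0, 1]")
        if a == b:
            n_self += 1
            continue
        if score >= score_threshold:
            kept.append(Interaction(a, b, score))
    if n_self:
        logger.warning("dropped %d self-interaction rows", n_self)
    if not kept:
        logger.warning("no interactions passed the %.3f threshold", score_threshold)
    return kept


def build_network(interactions: Iterable[Interaction]) -> Network:
    """Materialise a simple undirected graph from filtered interactions.

    Duplicate pairs (in either orientation) collapse to a single edge and
    self-loops are dropped with a logged count.
    """
    g = nx.Graph()
    n_self = 0
    for it in interactions:
        if it.protein_a == it.protein_b:
            n_self += 1
            continue
        g.add_edge(it.protein_a, it.protein_b)
    if n_self:
        logger.warning("dropped %d self-loops while building the network", n_self)
    return g


def seed_network(network: Network, seeds: Sequence[str]) -> Network:
    """Induced subgraph on the seeds plus all of their direct neighbours.

    Seeds absent from ``network`` are retained as isolated nodes with a
    logged warning so downstream profiles can be reported as degenerate.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    keep: set[str] = set(seeds)
    missing = [s for s in seeds if s not in network]
    if missing:
        logger.warning("%d seed(s) absent from network: %s", len(missing), missing)
    for s in seeds:
        if s in network:
            keep.update(network.neighbors(s))
    sub = network.subgraph(k for k in keep if k in network).copy()
    sub.add_nodes_from(missing)
    return sub


def read_mapping(path: str | Path) -> dict[str, MappingRow]:
    """Read a 4-column TSV of (query, reference, identity, coverage) and keep
    the best hit per query.

    Best hit: highest identity, ties broken by highest coverage, then by
    lexicographically smallest reference id.  An exact duplicate of the
    winning row (same identity, coverage and reference) is an error.
    """
    path = Path(path)
    best: dict[str, MappingRow] = {}
    counts: dict[tuple, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                row = MappingRow(
                    fields[0].strip(),
                    fields[1].strip(),
                    float(fields[2]),
                    float(fields[3]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if not (0.0 <= row.identity <= 100.0 and 0.0 <= row.coverage <= 100.0):
                raise ValueError(f"{path}:{lineno}: identity/coverage outside [0, 100]")
            key = (row.query, row.identity, row.coverage, row.reference)
            counts[key] = counts.get(key, 0) + 1

            cur = best.get(row.query)
            if cur is None or _hit_rank(row) > _hit_rank(cur):
                best[row.query] = row
    for (query, ident, cov, ref), n in counts.items():
        winner = best[query]
        if n > 1 and (ident, cov, ref) == (winner.identity, winner.coverage, winner.reference):
            raise ValueError(
                f"ambiguous mapping for query {query!r}: duplicated best hit {ref!r}"
            )
    return best


def _hit_rank(row: MappingRow) -> tuple:
    # lexicographically *smaller* reference wins ties, hence the negation trick
    return (row.identity, row.coverage, _NegStr(row.reference))


class _NegStr(str):
    """String whose ordering is reversed, for descending-sort tie-breaks."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def write_edgelist(network: Network, path: str | Path) -> None:
    """Write the network as a reproducible two-column edge-list TSV.

    Node ids are sorted lexicographically within each row and rows are
    sorted lexicographically across the file.
    """
    rows = sorted(tuple(sorted(map(str, e))) for e in network.edges())
    path = Path(path)
    with path.open("w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
        # isolated nodes are recorded as single-column rows so the node set
        # round-trips
        for node in sorted(str(n) for n in network.nodes() if network.degree(n) == 0):
            fh.write(f"{node}\n")


def read_edgelist(path: str | Path) -> Network:
    """Read an edge-list TSV written by :func:`write_edgelist`."""
    g = nx.Graph()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 1:
                g.add_node(fields[0])
            elif len(fields) >= 2:
                if fields[0] == fields[1]:
                    raise ValueError(f"{path}:{lineno}: self-loop in edge list")
                g.add_edge(fields[0], fields[1])
    return g
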