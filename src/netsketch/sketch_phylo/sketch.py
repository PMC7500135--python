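"""Bottom-s MinHash sketching of genomes and sketch-based distance estimation.

A genome is reduced to the set of its canonical k-mers (the lexicographic
minimum of each k-mer and its reverse complement), each k-mer is hashed with
a seeded 64-bit mixing hash, and the ``s`` smallest hash values form the
sketch.  The Jaccard index of two genomes is estimated from the bottom-s
values of the merged sketch, and converted to a nucleotide divergence
estimate in one of two ways:

* ``p`` (default): the proportion-of-differences estimate
  ``1 - (2j/(1+j)) ** (1/k)``, the exact inversion of the expected k-mer
  survival probability ``(1-p)**k`` — an estimator of the p-distance itself.
* ``mash``: the classical Poisson-model distance
  ``-(1/k) * ln(2j/(1+j))``, which approaches ``-ln(1-p)`` and therefore
  overshoots the p-distance for divergent genomes.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_KMER_SIZE = 16
DEFAULT_SKETCH_SIZE = 5000
DEFAULT_HASH_SEED = 42

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")
_MASK64 = (1 << 64) - 1


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of one genome."""

    label: str
    kmer_size: int
    sketch_size: int
    hash_seed: int
    hashes: tuple[int, ...]  # sorted ascending, strictly increasing

    def params(self) -> tuple[int, int, int]:
        return (self.kmer_size, self.sketch_size, self.hash_seed)


def canonical_kmers(sequence: str, kmer_size: int) -> set[str]:
    """Canonical k-mer set of a nucleotide sequence.

    Each window of ``kmer_size`` consecutive A/C/G/T symbols contributes
    ``min(window, reverse_complement(window))``; windows containing any other
    symbol (N, gaps, IUPAC ambiguity codes) are skipped.  Case-insensitive.
    """
    if kmer_size < 2:
        raise ValueError("kmer_size must be >= 2")
    seq = sequence.upper()
    n = len(seq)
    out: set[str] = set()
    if n < kmer_size:
        return out
    bad = [i for i, c in enumerate(seq) if c not in _VALID]
    if bad:
        bad_arr = np.array(bad)
        for i in range(n - kmer_size + 1):
            # window [i, i+k) is clean iff no bad position falls inside it
            j = np.searchsorted(bad_arr, i)
            if j < len(bad_arr) and bad_arr[j] < i + kmer_size:
                continue
            w = seq[i : i + kmer_size]
            rc = w.translate(_COMPLEMENT)[::-1]
            out.add(w if w <= rc else rc)
    else:
        for i in range(n - kmer_size + 1):
            w = seq[i : i + kmer_size]
            rc = w.translate(_COMPLEMENT)[::-1]
            out.add(w if w <= rc else rc)
    return out


def _mix64(x: int) -> int:
    """SplitMix64 finalizer: a well-dispersed 64-bit mixing function."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def hash_kmer(kmer: str, seed: int) -> int:
    """Seeded deterministic 64-bit hash of a k-mer string.

    Chains the SplitMix64 finalizer over 8-byte chunks of the k-mer; stable
    across processes and platforms (unlike the builtin ``hash``).
    """
    h = _mix64(seed & _MASK64)
    data = kmer.encode("ascii")
    for i in range(0, len(data), 8):
        h = _mix64(h ^ int.from_bytes(data[i : i + 8], "little"))
    return h


def bottom_sketch(
    kmers: Iterable[str],
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
    label: str = "",
    kmer_size: int | None = None,
) -> Sketch:
    """Keep the ``sketch_size`` smallest 64-bit k-mer hashes (all, if fewer)."""
    if sketch_size < 1:
        raise ValueError("sketch_size must be >= 1")
    kmers = set(kmers)
    if kmer_size is None:
        kmer_size = len(next(iter(kmers))) if kmers else 0
    if not kmers:
        logger.warning("empty k-mer set for %r: empty sketch", label)
        return Sketch(label, kmer_size, sketch_size, hash_seed, ())
    hashes = {hash_kmer(k, hash_seed) for k in kmers}
    bottom = heapq.nsmallest(sketch_size, hashes)
    return Sketch(label, kmer_size, sketch_size, hash_seed, tuple(sorted(bottom)))


def sketch_sequence(
    sequence: str,
    kmer_size: int = DEFAULT_KMER_SIZE,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
    label: str = "",
) -> Sketch:
    """Convenience: canonical k-mers then bottom sketch of one sequence."""
    return bottom_sketch(
        canonical_kmers(sequence, kmer_size),
        sketch_size=sketch_size,
        hash_seed=hash_seed,
        label=label,
        kmer_size=kmer_size,
    )


def jaccard(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s Jaccard estimate between two sketches.

    Among the s smallest hashes of the union of the two sketches, the
    fraction present in both.  Exact set Jaccard whenever the sketch size is
    at least the union cardinality.
    """
    if a.params() != b.params():
        raise ValueError(
            f"sketch parameter mismatch: {a.params()} vs {b.params()}"
        )
    set_a, set_b = set(a.hashes), set(b.hashes)
    union = set_a | set_b
    if not union:
        raise ValueError("cannot compare two empty sketches")
    merged = heapq.nsmallest(a.sketch_size, union)
    shared = sum(1 for h in merged if h in set_a and h in set_b)
    return shared / len(merged)


def mash_distance(j: float, kmer_size: int, cap: float = 1.0) -> float:
    """Poisson-model Mash distance ``-(1/k) * ln(2j/(1+j))``.

    ``j = 1`` gives exactly 0; ``j = 0`` returns the finite ``cap`` so that
    downstream matrices stay tree-buildable.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard estimate outside [0, 1]: {j}")
    if j == 0.0:
        return cap
    return max(0.0, -math.log(2.0 * j / (1.0 + j)) / kmer_size)


def p_distance(j: float, kmer_size: int, cap: float = 1.0) -> float:
    """Proportion-of-differences estimate ``1 - (2j/(1+j)) ** (1/k)``.

    Inverts the expected clean-window probability ``(1-p)**k``, so it
    estimates the substitution proportion itself without the logarithmic
    inflation of :func:`mash_distance` at high divergence.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard estimate outside [0, 1]: {j}")
    if j == 0.0:
        return cap
    return max(0.0, 1.0 - (2.0 * j / (1.0 + j)) ** (1.0 / kmer_size))


def correct_distance(p: float) -> float:
    """Jukes-Cantor-style correction ``-(3/4) * ln(1 - 4p/3)``.

    Converts a proportion of differing sites into an evolutionary distance
    (substitutions per site); undefined at ``p >= 0.75``.
    """
    if not 0.0 <= p < 0.75:
        raise ValueError(f"correction undefined for p = {p} (requires 0 <= p < 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


class DistanceMatrix:
    """Symmetric labelled distance matrix with a zero diagonal."""

    def __init__(self, labels: Sequence[str], values):
        values = np.asarray(values, dtype=float)
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (values < -1e-12).any():
            raise ValueError("negative distances")
        self.labels = labels
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def permuted(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in order]
        return DistanceMatrix(order, self.values[np.ix_(idx, idx)])

    def to_phylip(self, path: str | Path) -> None:
        """Write a PHYLIP square distance matrix."""
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(f"{v:.9f}" for v in row)
                fh.write(f"{label}\t{cells}\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with Path(path).open() as fh:
            header = fh.readline().split()
            if not header:
                raise ValueError(f"{path}: empty PHYLIP file")
            n = int(header[0])
            labels, rows = [], []
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                labels.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
            if len(labels) != n:
                raise ValueError(f"{path}: expected {n} rows, found {len(labels)}")
        return cls(labels, np.array(rows))


def distance_matrix(
    sketches: Sequence[Sketch],
    estimator: str = "p",
    correction: bool = False,
    cap: float = 1.0,
) -> DistanceMatrix:
    """All-pairs sketch distances.

    ``estimator`` selects :func:`p_distance` (default) or
    :func:`mash_distance`; ``correction`` additionally applies
    :func:`correct_distance` (off by default — raw distance is primary).
    """
    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches")
    if estimator not in ("p", "mash"):
        raise ValueError(f"unknown estimator {estimator!r}")
    labels = [s.label for s in sketches]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sketch labels")
    conv = p_distance if estimator == "p" else mash_distance
    n = len(sketches)
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            dist = conv(jaccard(sketches[i], sketches[k]), sketches[i].kmer_size, cap)
            if correction:
                dist = correct_distance(dist)
            d[i, k] = d[k, i] = dist
    return DistanceMatrix(labels, d)
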