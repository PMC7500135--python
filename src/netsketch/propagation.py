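"""Shell decomposition and signal-propagation profiling of seeded networks.

A seed's neighbourhood is decomposed into breadth-first shells S(0), S(1),
... S(r_max), where S(r) holds the nodes at shortest-path distance exactly r
(each node is counted once, in the shell of its first appearance).  The
propagation profile |D(r)| is the probability mass of reachable nodes at
distance r: it rises roughly exponentially while the network expands,
peaks at the saturation radius r_s, and decays as the shells contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .net_io import Network

logger = logging.getLogger(__name__)

DEFAULT_R_MAX = 8


@dataclass(frozen=True)
class DegreeStats:
    """First and second degree moments and the derived expansion quantities.

    ``alpha_paper`` is the raw moment ratio <k^2>/<k> (the conventional
    "rate of network expansion"); ``branching`` is the mean excess degree
    (<k^2> - <k>)/<k>, the expected number of onward links when arriving at a
    node along an edge, which governs shell-to-shell growth; ``prefactor`` is
    <k^2>/(<k^2> - <k>).
    """

    mean_degree: float
    second_moment: float
    alpha_paper: float
    branching: float
    prefactor: float


@dataclass(frozen=True)
class ShellDecomposition:
    """Breadth-first shells around a seed, truncated at ``r_max``."""

    seed: str
    shells: tuple[frozenset, ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.shells)

    @property
    def n_reachable(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True)
class PropagationProfile:
    """Per-seed propagation profile.

    ``d_of_r[r]`` is |D(r)|, the fraction of reachable nodes at distance r;
    the values sum to 1.  ``growth_rate`` is the least-squares slope of
    log |D(r)| over the rising regime 1 <= r <= r_s (NaN when fewer than two
    points exist).  ``degenerate`` flags seeds that reach nothing beyond
    themselves.
    """

    seed: str
    shell_sizes: tuple[int, ...]
    d_of_r: tuple[float, ...]
    growth_rate: float
    r_s: int
    degenerate: bool = field(default=False)


def hub_degrees(network: Network, seeds: Sequence[str]) -> list[tuple[str, int]]:
    """Degrees of the seed nodes, ranked by degree descending.

    Ties break lexicographically by node id; seeds absent from the network
    report degree 0.
    """
    pairs = [(s, network.degree(s) if s in network else 0) for s in seeds]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def degree_stats(network: Network) -> DegreeStats:
    """Degree moments over *all* nodes of the network (degree-0 included).

    Raises
    ------
    ValueError
        If the network has no edges (degenerate second-moment statistics).
    """
    if network.number_of_edges() == 0:
        raise ValueError("degree statistics are degenerate on an edgeless network")
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    k1 = degrees.mean()
    k2 = (degrees**2).mean()
    branching = (k2 - k1) / k1
    prefactor = k2 / (k2 - k1) if k2 > k1 else math.inf
    return DegreeStats(
        mean_degree=float(k1),
        second_moment=float(k2),
        alpha_paper=float(k2 / k1),
        branching=float(branching),
        prefactor=float(prefactor),
    )


def shell_decomposition(
    network: Network, seed: str, r_max: int = DEFAULT_R_MAX
) -> ShellDecomposition:
    """Decompose the seed's reachable set into breadth-first distance shells.

    Every node appears only in the shell of its shortest-path distance from
    the seed; the decomposition is truncated at ``r_max``.
    """
    if seed not in network:
        raise KeyError(f"seed {seed!r} not in network")
    if r_max < 0:
        raise ValueError("r_max must be >= 0")
    dist = nx.single_source_shortest_path_length(network, seed, cutoff=r_max)
    shells: list[set] = [set() for _ in range(max(dist.values()) + 1)]
    for node, r in dist.items():
        shells[r].add(node)
    return ShellDecomposition(seed=str(seed), shells=tuple(map(frozenset, shells)))


def saturation_radius(d_of_r: Sequence[float]) -> int:
    """Smallest r at which |D(r)| attains its maximum (the first peak)."""
    if len(d_of_r) == 0:
        raise ValueError("empty |D(r)| sequence")
    return int(np.argmax(d_of_r))  # argmax returns the first maximum


def propagation_profile(decomp: ShellDecomposition) -> PropagationProfile:
    """Empirical propagation profile of a shell decomposition.

    |D(r)| = |S(r)| / sum_r' |S(r')|; r_s is the first peak of |D(r)|;
    growth_rate is the least-squares slope of log |D(r)| for 1 <= r <= r_s.
    """
    sizes = decomp.sizes
    total = sum(sizes)
    if total == 0:
        raise ValueError("empty shell decomposition")
    d = tuple(s / total for s in sizes)
    if total == 1:  # isolated seed: only S(0) is populated
        logger.warning("seed %r is isolated; degenerate profile", decomp.seed)
        return PropagationProfile(
            seed=decomp.seed,
            shell_sizes=sizes,
            d_of_r=d,
            growth_rate=math.nan,
            r_s=0,
            degenerate=True,
        )
    r_s = saturation_radius(d)
    growth = _rising_slope(d, r_s)
    return PropagationProfile(
        seed=decomp.seed,
        shell_sizes=sizes,
        d_of_r=d,
        growth_rate=growth,
        r_s=r_s,
        degenerate=False,
    )


def _rising_slope(d: Sequence[float], r_s: int) -> float:
    rs = [r for r in range(1, r_s + 1) if d[r] > 0]
    if len(rs) < 2:
        return math.nan
    slope, _ = np.polyfit(rs, np.log([d[r] for r in rs]), 1)
    return float(slope)


def model_profile(stats: DegreeStats, r_values: Sequence[int]) -> list[float]:
    """Exponential-growth model of the rising regime.

    Returns ``prefactor * branching ** r`` for each r: the expected shell
    growth predicted by the degree moments, valid while the network expands.
    """
    if not stats.branching > 0:
        raise ValueError("no expansion regime: branching factor must be > 0")
    return [stats.prefactor * stats.branching**r for r in r_values]


def analyze_seeds(
    network: Network, seeds: Sequence[str], r_max: int = DEFAULT_R_MAX
) -> list[PropagationProfile]:
    """One independently computed propagation profile per seed.

    Seeds missing from the network yield flagged degenerate profiles
    (|D(0)| = 1) rather than failures.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    profiles = []
    for seed in seeds:
        if seed not in network:
            logger.warning("seed %r absent from network; degenerate profile", seed)
            profiles.append(
                PropagationProfile(
                    seed=str(seed),
                    shell_sizes=(1,),
                    d_of_r=(1.0,),
                    growth_rate=math.nan,
                    r_s=0,
                    degenerate=True,
                )
            )
        else:
            profiles.append(propagation_profile(shell_decomposition(network, seed, r_max)))
    return profiles


def summarize(network: Network, profiles: Sequence[PropagationProfile]) -> pd.DataFrame:
    """Per-seed report table: degree, r_s, growth rate and peak |D(r)|."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "seed": p.seed,
                "degree": network.degree(p.seed) if p.seed in network else 0,
                "r_s": p.r_s,
                "growth_rate": p.growth_rate,
                "peak_d": max(p.d_of_r),
                "n_reachable": sum(p.shell_sizes),
                "degenerate": p.degenerate,
            }
        )
    return pd.DataFrame(rows)


def profiles_table(profiles: Sequence[PropagationProfile]) -> pd.DataFrame:
    """Long-form table of |D(r)| values (columns: seed, r, shell_size, D_of_r)."""
    rows = []
    for p in profiles:
        for r, (size, d) in enumerate(zip(p.shell_sizes, p.d_of_r)):
            rows.append({"seed": p.seed, "r": r, "shell_size": size, "D_of_r": d})
    return pd.DataFrame(rows)


def plot_profiles(profiles: Sequence[PropagationProfile], path) -> None:
    """Optional |D(r)| vs r figure, one line per seed (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(range(len(p.d_of_r)), p.d_of_r, marker="o", label=p.seed)
    ax.set_xlabel("r")
    ax.set_ylabel("|D(r)|")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
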