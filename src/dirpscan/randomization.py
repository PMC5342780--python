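"""Null models: degree-preserving rewiring, random pair sets, empirical p-values.

The network null randomly permutes the partners of each node while keeping its
degree fixed (double-edge swaps with rejection of self-loops and multi-edges).
Empirical p-values use the permutation-standard add-one estimator
``p = (r + 1) / (n + 1)``, so with 100 replicates the smallest attainable
p-value is 1/101; significance below 0.01 therefore requires the observed
statistic to be more extreme than every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NullEnsemble",
    "replicate_seed",
    "rewire_preserving_degree",
    "empirical_pvalue",
    "sample_random_pairs",
    "simulate_commute_time",
]

DEFAULT_REPLICATES = 100


@dataclass(frozen=True)
class NullEnsemble:
    """Per-replicate values of a statistic under a null model."""

    values: np.ndarray
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0:
            raise ValueError("null ensemble is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("null ensemble contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)


def replicate_seed(seed: int, index: int) -> int:
    """Derived seed for replicate ``index`` (kept below 2**31)."""
    return (int(seed) + int(index)) % (2**31 - 1)


def rewire_preserving_degree(
    net: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomisation by double-edge swaps with rejection.

    ``n_swaps`` swap *attempts* are made (default ``10 * |E|``); a proposed swap
    replacing edges (a,b),(c,d) with (a,d),(c,b) is rejected whenever it would
    create a self-loop or a duplicate edge.  Graphs admitting no valid swap
    (e.g. a single edge) come back unchanged.
    """
    if n_swaps is not None and n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = np.random.default_rng(seed)
    out = net.copy()
    edges = [tuple(sorted(e)) for e in out.edges()]
    m = len(edges)
    if m < 2:
        return out
    if n_swaps is None:
        n_swaps = 10 * m
    edge_set = set(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # random orientation of the second edge
        if rng.integers(0, 2):
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    out.remove_edges_from(list(out.edges()))
    out.add_edges_from(edges)
    return out


def empirical_pvalue(observed: float, null: NullEnsemble, tail: str = "greater") -> float:
    """Add-one empirical p-value ``(r + 1) / (n + 1)``; ties count as extreme."""
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    values = null.values
    n = values.size
    if tail == "greater":
        r = int(np.sum(values >= observed))
    elif tail == "less":
        r = int(np.sum(values <= observed))
    elif tail == "two_sided":
        center = float(values.mean())
        r = int(np.sum(np.abs(values - center) >= abs(observed - center)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (r + 1) / (n + 1)


def sample_random_pairs(
    universe: Sequence, size: int, n_sets: int = DEFAULT_REPLICATES, seed: int = 0
) -> list[list]:
    """``n_sets`` sets of ``size`` distinct pairs sampled without replacement.

    Sampling is without replacement *within* a set; the same pair may of course
    recur across sets.  Matches the negative-control construction in which
    random pair sets keep the size of the observed set.
    """
    universe = list(universe)
    if size > len(universe):
        raise ValueError("requested set size exceeds the pair universe")
    out = []
    for rep in range(n_sets):
        rng = np.random.default_rng(replicate_seed(seed, rep))
        idx = rng.choice(len(universe), size=size, replace=False)
        out.append([universe[i] for i in sorted(idx)])
    return out


def simulate_commute_time(
    net: nx.Graph, a: str, b: str, n_walks: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo commute time: mean round-trip steps of a random walk a->b->a.

    Independent of the kernel machinery (pure neighbour-table simulation);
    returns (mean, standard error of the mean).
    """
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    neighbors = [np.array([index[v] for v in net[u]], dtype=np.int64) for u in nodes]
    start, target = index[a], index[b]
    times = np.empty(n_walks)
    for w in range(n_walks):
        steps = 0
        pos = start
        for goal in (target, start):
            while pos != goal:
                nbrs = neighbors[pos]
                pos = int(nbrs[rng.integers(0, len(nbrs))])
                steps += 1
        times[w] = steps
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(n_walks))
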