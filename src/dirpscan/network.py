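"""Protein–protein interaction graphs and kernel-based node distances.

An interaction network is an undirected simple graph of protein identifiers
(held as a :class:`networkx.Graph`).  Node similarity is measured with two
Laplacian kernels:

* the **diffusion kernel** ``K = exp(-beta * L)`` with ``L = D - A``, which
  models heat spread / lazy random-walk communication between nodes; and
* the **commute-time kernel** ``K = L^+`` (Moore–Penrose pseudo-inverse of the
  Laplacian), whose quadratic form gives the expected round-trip length of a
  random walk, ``C(i, j) = 2m * (K_ii + K_jj - 2 K_ij)``.

Kernel similarities are turned into distances by cosine-normalising the kernel
to an association probability ``p_ij = K_ij / sqrt(K_ii * K_jj)`` (in ``(0, 1]``
for PSD kernels, by Cauchy–Schwarz) and taking ``d_ij = -ln(p_ij)``.

Highly connected hubs short-circuit every path and are removed before kernel
computation (default: degree >= 300).  Kernels are computed on the largest
connected component; node pairs spanning components are *unreachable* and carry
no finite distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "KernelMatrix",
    "NetworkDistanceMatrix",
    "load_network",
    "read_edge_list",
    "remove_hubs",
    "largest_component",
    "diffusion_kernel",
    "commute_time_kernel",
    "commute_times",
    "kernel_to_distance",
]

logger = logging.getLogger(__name__)

#: Alias: interaction networks are plain undirected simple graphs.
InteractionNetwork = nx.Graph

# Kernel entries can dip below zero numerically (and L+ genuinely has negative
# off-diagonal entries); probabilities are floored here before the logarithm,
# making such pairs effectively infinitely distant.
PROBABILITY_FLOOR = 1e-12

DEFAULT_HUB_DEGREE_CUTOFF = 300


def load_network(records: Iterable[Sequence[str]], dedupe: bool = True) -> nx.Graph:
    """Build a simple undirected graph from identifier-pair records.

    Self-loops are dropped (with a warning); duplicate edges collapse.  A
    malformed record raises ``ValueError`` naming its (1-based) position.
    """
    net = nx.Graph()
    for lineno, rec in enumerate(records, start=1):
        if len(rec) < 2 or not rec[0] or not rec[1]:
            raise ValueError(f"malformed interaction record at line {lineno}: {rec!r}")
        a, b = str(rec[0]), str(rec[1])
        if a == b:
            logger.warning("dropping self-interaction %r (line %d)", a, lineno)
            net.add_node(a)
            continue
        if not dedupe and net.has_edge(a, b):
            raise ValueError(f"duplicate edge at line {lineno}: {a}-{b}")
        net.add_edge(a, b)
    return net


def read_edge_list(
    path: str | Path,
    comment: str = "#",
    physical_only: bool = False,
    physical_flag: str = "physical",
) -> nx.Graph:
    """Read a 2-column (plus optional evidence-type column) TSV edge list.

    With ``physical_only`` rows are kept only when the third column contains
    ``physical_flag`` (a minimal MITAB-like filter for direct physical
    interactions).
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(comment):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed interaction record at line {lineno}: {line!r}")
            if physical_only and (len(fields) < 3 or physical_flag not in fields[2]):
                continue
            records.append(fields[:2])
    return load_network(records)


def remove_hubs(net: nx.Graph, cutoff: int = DEFAULT_HUB_DEGREE_CUTOFF) -> nx.Graph:
    """Drop every node with degree >= ``cutoff`` (single pass on input degrees).

    Removal is not iterated: degrees are evaluated once on the input graph, so
    nodes whose degree falls below the cutoff *because* a hub was removed are
    retained.
    """
    if cutoff < 1:
        raise ValueError("hub degree cutoff must be >= 1")
    hubs = [n for n, d in net.degree() if d >= cutoff]
    out = net.copy()
    out.remove_nodes_from(hubs)
    if hubs:
        logger.info("removed %d hub nodes (degree >= %d)", len(hubs), cutoff)
    return out


def largest_component(net: nx.Graph) -> list[str]:
    """Sorted node list of the largest connected component (ties: lexicographic)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps[0]


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric PSD node-similarity matrix over the largest component."""

    nodes: tuple[str, ...]
    values: np.ndarray
    kind: str
    n_edges: int = 0
    beta: float | None = None
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def value(self, a: str, b: str) -> float:
        """Kernel similarity for a node pair; KeyError if outside the component."""
        return float(self.values[self._index[a], self._index[b]])

    def get(self, a: str, b: str, default: float = np.nan) -> float:
        """Like :meth:`value` but returns ``default`` for unreachable pairs."""
        if a in self._index and b in self._index:
            return self.value(a, b)
        return default

    def reachable(self, a: str, b: str) -> bool:
        return a in self._index and b in self._index


def _component_laplacian(net: nx.Graph) -> tuple[list[str], np.ndarray]:
    nodes = largest_component(net)
    sub = net.subgraph(nodes)
    a = nx.to_numpy_array(sub, nodelist=nodes, dtype=float)
    lap = np.diag(a.sum(axis=1)) - a
    return nodes, lap


def diffusion_kernel(net: nx.Graph, beta: float = 1.0) -> KernelMatrix:
    """Laplacian exponential diffusion kernel ``exp(-beta * L)``.

    Computed spectrally (eigendecomposition of the symmetric Laplacian) on the
    largest connected component, with nodes in lexicographic order, so the
    result is exactly symmetric.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    nodes, lap = _component_laplacian(net)
    w, u = np.linalg.eigh(lap)
    k = (u * np.exp(-beta * w)) @ u.T
    k = (k + k.T) / 2.0
    m = net.subgraph(nodes).number_of_edges()
    return KernelMatrix(tuple(nodes), k, kind="diffusion", n_edges=m, beta=beta)


def commute_time_kernel(net: nx.Graph) -> KernelMatrix:
    """Commute-time kernel: Moore–Penrose pseudo-inverse of the Laplacian.

    Defined on the largest connected component, where L has exactly one zero
    eigenvalue (dropped in the pseudo-inversion).
    """
    nodes, lap = _component_laplacian(net)
    m = net.subgraph(nodes).number_of_edges()
    if m == 0:
        raise ValueError("kernel undefined: component has no edges")
    w, u = np.linalg.eigh(lap)
    tol = max(len(nodes), 1) * np.finfo(float).eps * max(w.max(), 1.0)
    inv = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
    k = (u * inv) @ u.T
    k = (k + k.T) / 2.0
    return KernelMatrix(tuple(nodes), k, kind="commute_time", n_edges=m)


def commute_times(kernel: KernelMatrix) -> np.ndarray:
    """Pairwise commute times ``C(i,j) = 2m (K_ii + K_jj - 2 K_ij)`` from L+."""
    if kernel.kind != "commute_time":
        raise ValueError("commute times require the commute-time kernel")
    diag = np.diag(kernel.values)
    c = 2.0 * kernel.n_edges * (diag[:, None] + diag[None, :] - 2.0 * kernel.values)
    np.fill_diagonal(c, 0.0)
    return np.maximum(c, 0.0)


@dataclass(frozen=True)
class NetworkDistanceMatrix:
    """Association probabilities ``p`` and distances ``d = -ln(p)`` per pair."""

    nodes: tuple[str, ...]
    p: np.ndarray
    d: np.ndarray
    kind: str
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})

    def probability(self, a: str, b: str) -> float:
        return float(self.p[self._index[a], self._index[b]])

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def to_frame(self):
        """Long-format table (node_a, node_b, p, d) over unordered pairs."""
        import pandas as pd

        rows = []
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.nodes[i], self.nodes[j], self.p[i, j], self.d[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "p", "d"])


def kernel_to_distance(
    kernel: KernelMatrix, floor: float = PROBABILITY_FLOOR
) -> NetworkDistanceMatrix:
    """Cosine-normalise a kernel and take ``-ln`` to obtain distances.

    ``p_ij = K_ij / sqrt(K_ii K_jj)`` lies in ``(0, 1]`` for PSD kernels with a
    positive diagonal; non-positive entries are floored at ``floor`` so the
    logarithm stays finite (such pairs are effectively infinitely distant).
    """
    diag = np.diag(kernel.values)
    if np.any(diag <= 0):
        raise ValueError("kernel diagonal must be strictly positive")
    p = kernel.values / np.sqrt(np.outer(diag, diag))
    p = np.clip(p, floor, 1.0)
    np.fill_diagonal(p, 1.0)
    d = -np.log(p)
    np.fill_diagonal(d, 0.0)
    return NetworkDistanceMatrix(kernel.nodes, p, d, kind=kernel.kind)
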