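"""Patristic distances from Newick trees, with exponential rescaling.

The patristic distance between two leaves is the sum of branch lengths along
the unique path connecting them.  For joint plotting with network distances
the raw distances are rescaled with a strictly monotone exponential transform
``d' = exp(lambda * d) - 1`` (``d' = 0`` at ``d = 0``), which stretches the
divergent tail of the tree without reordering any pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "PhyloDistanceMatrix",
    "parse_tree",
    "read_tree",
    "patristic_distances",
    "normalize_phylo",
]


def parse_tree(text: str) -> dendropy.Tree:
    """Parse a Newick string into a tree, validating labels and branch lengths.

    Raises ``ValueError`` on syntax errors, duplicate leaf labels, negative or
    missing branch lengths (the root edge may legitimately carry none).
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    if not labels:
        raise ValueError("tree has no labelled leaves")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    return parse_tree(Path(path).read_text())


@dataclass(frozen=True)
class PhyloDistanceMatrix:
    """Leaf-indexed patristic distances, optionally with a normalised copy."""

    leaves: tuple[str, ...]
    raw: np.ndarray
    norm: np.ndarray | None = None
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.leaves)})

    def distance(self, a: str, b: str, normalized: bool = False) -> float:
        values = self.norm if normalized else self.raw
        if normalized and values is None:
            raise ValueError("normalized distances not computed")
        return float(values[self._index[a], self._index[b]])

    def to_frame(self):
        import pandas as pd

        rows = []
        n = len(self.leaves)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (
                        self.leaves[i],
                        self.leaves[j],
                        self.raw[i, j],
                        np.nan if self.norm is None else self.norm[i, j],
                    )
                )
        return pd.DataFrame(rows, columns=["leaf_a", "leaf_b", "d_raw", "d_norm"])


def patristic_distances(
    tree: dendropy.Tree, height_normalize: bool = False
) -> PhyloDistanceMatrix:
    """Pairwise path-length (patristic) distances between all leaves.

    With ``height_normalize`` distances are divided by the maximum root-to-leaf
    depth, putting trees on a comparable scale.
    """
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaves)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[leaves[i]], taxa[leaves[j]])
            raw[i, j] = raw[j, i] = d
    if height_normalize:
        height = max(
            leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        )
        if height > 0:
            raw = raw / height
    return PhyloDistanceMatrix(tuple(leaves), raw)


def normalize_phylo(dm: PhyloDistanceMatrix, lam: float = 1.0) -> PhyloDistanceMatrix:
    """Rescale distances as ``d' = exp(lam * d) - 1`` (strictly increasing)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    norm = np.expm1(lam * dm.raw)
    np.fill_diagonal(norm, 0.0)
    return replace(dm, norm=norm)
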