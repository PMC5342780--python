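"""Synthetic study systems with known ground truth.

Three generators emulate the pipeline's inputs at desk scale so every stage is
testable without downloads:

* ``synth_network`` — a preferential-attachment interactome with a paralog
  family wired in.  Each *planted* pair shares an exact number of interaction
  partners (default 3, the shared-interactor median observed for real
  divergent-but-interacting pairs); all other family pairs share none, because
  partner assignments are drawn without replacement.
* ``synth_family_msa_tree`` — a duplicated family evolved down a two-clade
  ultrametric tree under a uniform per-site substitution process, giving the
  identity/patristic-distance gradient the analysis assumes.  Planted pair
  members sit in opposite clades (so the pairs are sequence-divergent), and
  designated alignment columns are overwritten to be conserved within each
  planted pair only (per-pair residues), plus one column conserved across the
  family but mismatched within every planted pair (the anti-conserved case).
* ``synth_complex`` — a toy two-chain complex of Cβ-level spheres on an
  idealised extended backbone, with a partner peptide hovering over designated
  contact residues at a distance that buries their solvent shell but not their
  sequence neighbours'.

The generator's defaults are the package's reference study conditions; sizes
mirror the real system where meaningful (35 family members, like the human
Ras family) and stay small enough for routine runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import AMINO_ACIDS, MultipleAlignment
from .phylogeny import parse_tree
from .structure import Atom, ComplexStructure, Residue, parse_structure

__all__ = ["SyntheticSpec", "SyntheticTruth", "synth_network", "synth_family_msa_tree", "synth_complex"]


def default_planted_pairs(n_pairs: int = 10, n_shared: int = 3) -> list[tuple[str, str, int]]:
    return [
        (f"RAS{2 * i + 1:02d}", f"RAS{2 * i + 2:02d}", n_shared) for i in range(n_pairs)
    ]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study system (seed is mandatory)."""

    seed: int
    # interactome
    n_background_nodes: int = 300
    attachment: int = 2  # preferential-attachment edges per new node
    member_degree: int = 3  # private background partners per family member
    # family
    n_family_members: int = 35
    planted_pairs: list[tuple[str, str, int]] = field(default_factory=default_planted_pairs)
    # alignment / tree
    msa_length: int = 160
    substitution_rate: float = 1.2  # substitutions per site per unit branch length
    tree_depth: float = 1.0
    clade_depth: float = 0.5
    n_conserved_columns: int = 6
    n_variable_columns: int = 1
    # toy complex
    peptide_length: int = 12
    contact_residues: tuple[int, ...] = (5, 6, 7)
    contact_distance: float = 5.5  # Å between facing residue spheres
    residue_spacing: float = 3.8  # Å along the chain

    def __post_init__(self) -> None:
        members = set(self.member_ids())
        for a, b, k in self.planted_pairs:
            if a not in members or b not in members:
                raise ValueError(f"planted pair ({a}, {b}) outside the family")
            if k < 0:
                raise ValueError("negative shared-partner count")
        if any(not 1 <= c <= self.peptide_length for c in self.contact_residues):
            raise ValueError("contact residues outside the peptide")
        if self.n_conserved_columns + self.n_variable_columns >= self.msa_length:
            raise ValueError("more planted columns than alignment columns")

    def member_ids(self) -> list[str]:
        return [f"RAS{i + 1:02d}" for i in range(self.n_family_members)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels of one synthetic system."""

    planted_pairs: tuple[tuple[str, str], ...]
    shared_partners: dict[tuple[str, str], tuple[str, ...]]
    family_ids: tuple[str, ...]
    conserved_columns: tuple[int, ...] = ()
    variable_columns: tuple[int, ...] = ()
    contacts: tuple[int, ...] = ()

    def decoy_pairs(self) -> list[tuple[str, str]]:
        planted = {tuple(sorted(p)) for p in self.planted_pairs}
        ids = sorted(self.family_ids)
        return [
            (a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if (a, b) not in planted
        ]


def synth_network(spec: SyntheticSpec) -> tuple[nx.Graph, SyntheticTruth]:
    """Background interactome plus family wiring with exact shared-partner counts."""
    rng = np.random.default_rng(spec.seed)
    background = nx.barabasi_albert_graph(
        spec.n_background_nodes, spec.attachment, seed=int(rng.integers(2**31 - 1))
    )
    net = nx.relabel_nodes(background, {i: f"BG{i:03d}" for i in background.nodes()})
    members = spec.member_ids()
    bg_nodes = sorted(net.nodes())

    planted = [tuple(sorted((a, b))) for a, b, _ in spec.planted_pairs]
    needed = sum(k for _, _, k in spec.planted_pairs) + spec.member_degree * len(members)
    if needed > len(bg_nodes):
        raise ValueError("background too small for requested partner counts")
    # one global draw without replacement: no two family members can share a
    # partner unless planted to
    pool = list(rng.permutation(bg_nodes))
    shared_map: dict[tuple[str, str], tuple[str, ...]] = {}
    for a, b, k in spec.planted_pairs:
        shared = [pool.pop() for _ in range(k)]
        shared_map[tuple(sorted((a, b)))] = tuple(sorted(shared))
        for partner in shared:
            net.add_edge(a, partner)
            net.add_edge(b, partner)
    for member in members:
        for _ in range(spec.member_degree):
            net.add_edge(member, pool.pop())
    truth = SyntheticTruth(
        planted_pairs=tuple(planted),
        shared_partners=shared_map,
        family_ids=tuple(members),
    )
    return net, truth


def _random_ultrametric(leaves: list[str], depth: float, rng: np.random.Generator) -> str:
    """Newick for a random ultrametric clade of total height ``depth``."""
    if len(leaves) == 1:
        return f"{leaves[0]}:{depth:.6f}"
    heights = np.sort(rng.uniform(0.05 * depth, depth, size=len(leaves) - 1))
    heights[-1] = depth
    clusters = [(leaf, 0.0) for leaf in leaves]
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, ha), (nb, hb) = clusters[i], clusters[j]
        node = (f"({na}:{h - ha:.6f},{nb}:{h - hb:.6f})", h)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [node]
    return clusters[0][0]


def synth_family_msa_tree(
    spec: SyntheticSpec,
) -> tuple[MultipleAlignment, "dendropy.Tree", SyntheticTruth]:  # noqa: F821
    """Family tree + evolved alignment with planted differential columns.

    Planted pair members are placed in opposite basal clades, so every planted
    pair is divergent (patristic distance ~= 2 * tree depth).  Pairwise
    identity decreases with patristic distance by construction of the
    substitution process.
    """
    rng = np.random.default_rng(spec.seed + 1)
    members = spec.member_ids()
    planted = [tuple(sorted((a, b))) for a, b, _ in spec.planted_pairs]
    left = [a for a, _, _ in spec.planted_pairs]
    right = [b for _, b, _ in spec.planted_pairs]
    free = [m for m in members if m not in set(left) | set(right)]
    # distribute unpaired members across the clades
    for i, m in enumerate(free):
        (left if i % 2 == 0 else right).append(m)

    stem = max(spec.tree_depth - spec.clade_depth, 0.0)
    newick = (
        f"({_sub(left, spec, rng)}:{stem:.6f},{_sub(right, spec, rng)}:{stem:.6f});"
    )
    tree = parse_tree(newick)

    # evolve sequences root -> leaves under uniform substitution
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    root_seq = rng.integers(0, len(aa), size=spec.msa_length)
    seqs: dict[str, np.ndarray] = {}

    def evolve(parent_seq: np.ndarray, node) -> None:
        for child in node.child_nodes():
            seq = parent_seq.copy()
            p_sub = 1.0 - np.exp(-spec.substitution_rate * (child.edge.length or 0.0))
            hit = rng.random(spec.msa_length) < p_sub
            if hit.any():
                shift = rng.integers(1, len(aa), size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % len(aa)
            if child.is_leaf():
                seqs[child.taxon.label] = seq
            else:
                evolve(seq, child)

    evolve(root_seq, tree.seed_node)

    # plant differential columns
    columns = rng.choice(spec.msa_length, size=spec.n_conserved_columns + spec.n_variable_columns, replace=False)
    conserved_cols = tuple(int(c) for c in columns[: spec.n_conserved_columns])
    variable_cols = tuple(int(c) for c in columns[spec.n_conserved_columns :])
    for col in conserved_cols:
        residues = rng.permutation(len(aa))[: len(planted)]
        for (a, b), res in zip(planted, residues):
            seqs[a][col] = res
            seqs[b][col] = res
    trp, cys = AMINO_ACIDS.index("W"), AMINO_ACIDS.index("C")
    for col in variable_cols:
        for m in members:
            seqs[m][col] = trp
        for a, _b in planted:  # break conservation inside each planted pair
            seqs[a][col] = cys

    rows = {m: "".join(aa[seqs[m]]) for m in members}
    msa = MultipleAlignment(rows=rows, reference_id=members[0])
    truth = SyntheticTruth(
        planted_pairs=tuple(planted),
        shared_partners={},
        family_ids=tuple(members),
        conserved_columns=conserved_cols,
        variable_columns=variable_cols,
    )
    return msa, tree, truth


def _sub(leaves: list[str], spec: SyntheticSpec, rng: np.random.Generator) -> str:
    return (
        f"({_random_ultrametric(leaves, spec.clade_depth, rng)})"
        if len(leaves) == 1
        else _random_ultrametric(leaves, spec.clade_depth, rng)
    )


def synth_complex(spec: SyntheticSpec, separation: float | None = None) -> tuple[ComplexStructure, SyntheticTruth]:
    """Toy two-chain complex with geometrically known contact residues.

    Chain A is an extended poly-alanine-like chain of single Cβ-level spheres;
    chain B hovers above the designated contact residues at ``contact_distance``
    (or ``separation`` when given, e.g. 100 Å for a no-contact control).  At the
    default geometry each contact sphere is occluded by exactly one partner
    sphere while sequence neighbours stay outside occlusion range.
    """
    dz = spec.contact_distance if separation is None else separation
    spacing = spec.residue_spacing

    def residue(number: int, x: float, z: float) -> Residue:
        atom = Atom(name="CB", element="C", coord=np.array([x, 0.0, z]), radius=1.70)
        return Residue(name="ALA", number=number, atoms=(atom,))

    chain_a = tuple(residue(i, (i - 1) * spacing, 0.0) for i in range(1, spec.peptide_length + 1))
    chain_b = tuple(
        residue(j + 1, (c - 1) * spacing, dz) for j, c in enumerate(spec.contact_residues)
    )
    cx = ComplexStructure(
        complex_id="SYNTH", chains={"A": chain_a, "B": chain_b}, ras_chain_id="A"
    )
    # round-trip through the PDB text path so downstream consumers see exactly
    # what a file-based run would
    cx = parse_structure(cx.to_pdb(), ras_chain="A", structure_id="SYNTH")
    truth = SyntheticTruth(
        planted_pairs=(),
        shared_partners={},
        family_ids=(),
        contacts=tuple(spec.contact_residues) if separation is None else (),
    )
    return cx, truth
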