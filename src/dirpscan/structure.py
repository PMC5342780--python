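"""Complex structures, ΔSASA binding interfaces, and position/interface overlap.

The binding interface of a complex is defined through solvent accessibility:
a residue of the designated Ras-family chain belongs to the interface when its
solvent-accessible surface area (SASA) computed for the chain *alone* exceeds
its SASA *within the complex* by more than a threshold (default 1.0 Å²), i.e.
surface gets buried on binding.  SASA is computed with the Shrake–Rupley
numerical method: each atom's solvent sphere (van der Waals radius + 1.4 Å
probe) is sampled with a deterministic golden-spiral point set (default 960
points) and the unoccluded fraction of points is converted to area.

Complexes are clustered into functional groups by Cα RMSD of their Ras chains
after optimal (Kabsch) superposition, with single-linkage merging under the
cutoff (default 1.0 Å); sequence-identical structures collapse first.

Overlap between a query position list (e.g. differentially conserved
positions) and the interfaces is tabulated per complex (match count and
percentage of the interface) and per position (number of matching complexes),
with a flanking class for positions that are not buried themselves but whose
two sequence neighbours are.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ras_annotations import (
    COMPLEX_CATEGORIES,
    COMPLEX_INTERFACES,
    FUNCTIONAL_REGIONS,
    parse_position,
)

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "FunctionalGroup",
    "InterfaceRegion",
    "MatchTable",
    "parse_structure",
    "sphere_points",
    "shrake_rupley",
    "residue_sasa",
    "interface_residues",
    "kabsch_rmsd",
    "cluster_complexes",
    "match_positions",
    "flanking_participation",
    "region_assignment",
    "round_half_down",
    "percent_int",
]

PROBE_RADIUS = 1.4  # water probe, Å
N_SPHERE_POINTS = 960
DELTA_SASA_THRESHOLD = 1.0  # Å², strict >
RMSD_CUTOFF = 1.0  # Å, single-linkage clustering

#: Bondi-type van der Waals radii by element (Å); fallback 1.8.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.80


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"bad coordinates for atom {self.name}: {self.coord}")
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.name}")
        object.__setattr__(self, "coord", coord)


@dataclass(frozen=True)
class Residue:
    name: str  # 3-letter code
    number: int  # author residue number
    atoms: tuple[Atom, ...]


@dataclass(frozen=True)
class ComplexStructure:
    """A (multi-chain) structure with a designated Ras-family chain.

    ``numbering_map`` optionally renumbers the Ras chain into reference
    (HRas-equivalent) positions; by default author numbering is used.
    """

    complex_id: str
    chains: dict[str, tuple[Residue, ...]]
    ras_chain_id: str
    numbering_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if self.ras_chain_id not in self.chains:
            raise ValueError(
                f"chain {self.ras_chain_id!r} absent from structure {self.complex_id}"
            )

    def reference_number(self, author_number: int) -> int:
        if self.numbering_map is None:
            return author_number
        return self.numbering_map[author_number]

    def atoms(self, chain_ids: list[str] | None = None) -> list[Atom]:
        chains = self.chains if chain_ids is None else {c: self.chains[c] for c in chain_ids}
        return [a for residues in chains.values() for r in residues for a in r.atoms]

    def ras_sequence(self) -> str:
        from Bio.Data.IUPACData import protein_letters_3to1

        out = []
        for res in self.chains[self.ras_chain_id]:
            out.append(protein_letters_3to1.get(res.name.capitalize(), "X"))
        return "".join(out)

    def ras_ca_coords(self) -> dict[int, np.ndarray]:
        """One backbone coordinate per Ras-chain residue (Cα, falling back to
        Cβ for reduced-representation models), keyed by author number."""
        coords = {}
        for res in self.chains[self.ras_chain_id]:
            names = {a.name: a.coord for a in res.atoms}
            pick = names.get("CA", names.get("CB"))
            if pick is None:
                pick = res.atoms[0].coord
            coords[res.number] = pick
        return coords

    def to_pdb(self) -> str:
        lines = []
        serial = 1
        for chain_id, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    lines.append(
                        f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} {chain_id}"
                        f"{res.number:4d}    "
                        f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      {residues[-1].name:>3s} {chain_id}")
        lines.append("END")
        return "\n".join(lines) + "\n"


def parse_structure(
    source: str, ras_chain: str, structure_id: str = "complex", include_het: bool = False
) -> ComplexStructure:
    """Parse PDB-format text (or a path) into a :class:`ComplexStructure`.

    Alternate locations resolve to the highest-occupancy conformer (Biopython's
    default); hydrogens are kept; HETATM records are dropped unless
    ``include_het`` (waters always dropped).  Van der Waals radii are assigned
    by element.
    """
    from Bio.PDB import PDBParser

    text = source
    if "\n" not in source:  # a path
        with open(source) as handle:
            text = handle.read()
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(structure_id, io.StringIO(text))[0]
    chains: dict[str, tuple[Residue, ...]] = {}
    for chain in model:
        residues = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag != " " and (not include_het or hetflag == "W"):
                continue
            atoms = []
            for atom in res:
                element = (atom.element or atom.get_name()[0]).upper()
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        coord=np.array(atom.get_coord(), dtype=float),
                        radius=ELEMENT_RADII.get(element, DEFAULT_RADIUS),
                    )
                )
            if atoms:
                residues.append(Residue(name=res.get_resname(), number=res.id[1], atoms=tuple(atoms)))
        if residues:
            chains[chain.id] = tuple(residues)
    if not chains:
        raise ValueError(f"no ATOM records in structure {structure_id}")
    if ras_chain not in chains:
        raise ValueError(f"chain {ras_chain!r} absent from structure {structure_id}")
    return ComplexStructure(structure_id, chains, ras_chain)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    atoms: list[Atom],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley method."""
    if not atoms:
        raise ValueError("no atoms")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.radius for a in atoms]) + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], radii[i] + radii.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return areas


def residue_sasa(
    cx: ComplexStructure,
    chain_ids: list[str] | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> dict[tuple[str, int], float]:
    """Per-residue SASA of the structure restricted to ``chain_ids`` (Å²)."""
    chains = list(cx.chains) if chain_ids is None else chain_ids
    atoms: list[Atom] = []
    owner: list[tuple[str, int]] = []
    for chain_id in chains:
        for res in cx.chains[chain_id]:
            for atom in res.atoms:
                atoms.append(atom)
                owner.append((chain_id, res.number))
    areas = shrake_rupley(atoms, probe_radius=probe_radius, n_points=n_points)
    out: dict[tuple[str, int], float] = {}
    for key, area in zip(owner, areas):
        out[key] = out.get(key, 0.0) + float(area)
    return out


@dataclass(frozen=True)
class InterfaceRegion:
    """Interface of one complex: buried Ras positions in reference numbering."""

    complex_id: str
    positions: frozenset[int]
    delta_sasa: dict[int, float] = field(default_factory=dict)
    category: str = ""


def interface_residues(
    cx: ComplexStructure,
    delta_threshold: float = DELTA_SASA_THRESHOLD,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> InterfaceRegion:
    """Ras residues losing more than ``delta_threshold`` Å² of SASA on binding.

    Compares the Ras chain computed in isolation (unbound state taken from the
    complex conformation) against the full complex; the comparison is strict
    (ΔSASA exactly at the threshold is excluded).
    """
    alone = residue_sasa(cx, [cx.ras_chain_id], probe_radius, n_points)
    bound = residue_sasa(cx, None, probe_radius, n_points)
    positions = set()
    deltas = {}
    for (chain_id, number), area in alone.items():
        delta = area - bound.get((chain_id, number), 0.0)
        if delta > delta_threshold:
            ref = cx.reference_number(number)
            positions.add(ref)
            deltas[ref] = round(float(delta), 3)
    return InterfaceRegion(cx.complex_id, frozenset(positions), deltas)


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Cα RMSD of two coordinate sets after optimal rigid superposition."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ValueError("need >= 3 paired atoms for superposition")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ pc.T).T - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


@dataclass(frozen=True)
class FunctionalGroup:
    """Structurally equivalent complexes (pairwise Cα RMSD under the cutoff)."""

    members: tuple[str, ...]
    representative: str
    max_rmsd: float


def cluster_complexes(
    structures: list[ComplexStructure], rmsd_cutoff: float = RMSD_CUTOFF
) -> list[FunctionalGroup]:
    """Single-linkage grouping of Ras chains by Kabsch-superposed Cα RMSD.

    Sequence-identical structures merge first (RMSD is still evaluated on them,
    so a perturbed identical-sequence copy can stay apart); superposition uses
    Cα atoms with common author numbering.
    """
    if not structures:
        raise ValueError("no structures to cluster")
    n = len(structures)
    coords = [s.ras_ca_coords() for s in structures]
    seqs = [s.ras_sequence() for s in structures]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = sorted(set(coords[i]) & set(coords[j]))
            if len(common) < 3:
                raise ValueError(
                    f"fewer than 3 common Cα atoms between "
                    f"{structures[i].complex_id} and {structures[j].complex_id}"
                )
            p = np.array([coords[i][k] for k in common])
            q = np.array([coords[j][k] for k in common])
            dist[i, j] = dist[j, i] = kabsch_rmsd(p, q)
    # single linkage under the cutoff, with identical sequences pre-linked
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i] == seqs[j] and dist[i, j] < rmsd_cutoff:
                union(i, j)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < rmsd_cutoff:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        ids = sorted(structures[i].complex_id for i in members)
        max_rmsd = max(
            (dist[i, j] for i in members for j in members if i < j), default=0.0
        )
        out.append(FunctionalGroup(tuple(ids), representative=ids[0], max_rmsd=float(max_rmsd)))
    return sorted(out, key=lambda g: g.representative)


def round_half_down(x: float, ndigits: int = 1) -> float:
    """Round with exact halves going down (the tabulation convention used here)."""
    factor = 10**ndigits
    return math.ceil(x * factor - 0.5) / factor


def percent_int(x: float) -> int:
    """Integer percentage with halves rounding up."""
    return int(math.floor(x + 0.5))


def curated_ras_interfaces() -> list[InterfaceRegion]:
    """The curated human Ras complex interfaces as :class:`InterfaceRegion` list."""
    return [
        InterfaceRegion(
            complex_id=cid,
            positions=frozenset(parse_position(p) for p in residues),
            category=COMPLEX_CATEGORIES.get(cid, ""),
        )
        for cid, residues in COMPLEX_INTERFACES.items()
    ]


@dataclass(frozen=True)
class MatchTable:
    """Two mutually consistent views of position/interface overlap."""

    per_complex: pd.DataFrame  # complex_id, interface_size, n_matches, ratio_pct, matches
    per_position: pd.DataFrame  # position, n_matches, complexes


def _positions_as_ints(positions) -> list[int]:
    return [parse_position(p) for p in positions]


def _interface_positions(interface: InterfaceRegion | tuple) -> frozenset[int]:
    if isinstance(interface, InterfaceRegion):
        return interface.positions
    raise TypeError("expected InterfaceRegion")


def match_positions(
    interfaces: list[InterfaceRegion], positions: list[str | int]
) -> MatchTable:
    """Overlap of a query position list with each complex interface.

    Per complex: how many query positions are buried in its interface and which
    share of the interface they cover (percentage, half-down to 1 d.p.).  Per
    position: in how many complexes it is buried.  Positions are compared as
    reference residue numbers.
    """
    query = _positions_as_ints(positions)
    labels = {parse_position(p): str(p) for p in positions}
    complex_rows = []
    pos_hits: dict[int, list[str]] = {q: [] for q in query}
    for region in interfaces:
        iface = _interface_positions(region)
        matched = sorted(q for q in query if q in iface)
        for q in matched:
            pos_hits[q].append(region.complex_id)
        size = len(iface)
        ratio = round_half_down(100.0 * len(matched) / size, 1) if size else 0.0
        complex_rows.append(
            dict(
                complex_id=region.complex_id,
                category=region.category,
                interface_size=size,
                n_matches=len(matched),
                ratio_pct=ratio,
                matches=",".join(labels[q] for q in matched),
            )
        )
    per_complex = pd.DataFrame(complex_rows)
    pos_rows = [
        dict(
            position=labels[q],
            residue_number=q,
            n_matches=len(hits),
            complexes=",".join(hits),
        )
        for q, hits in pos_hits.items()
    ]
    per_position = pd.DataFrame(
        pos_rows, columns=["position", "residue_number", "n_matches", "complexes"]
    )
    per_position = per_position.sort_values(
        ["n_matches", "residue_number"], ascending=[False, True]
    ).reset_index(drop=True)
    return MatchTable(per_complex=per_complex, per_position=per_position)


def flanking_participation(
    interfaces: list[InterfaceRegion],
    positions: list[str | int],
    same_complex: bool = False,
) -> pd.DataFrame:
    """Classify each query position as direct, flanked, or none.

    *direct*: buried in at least one interface.  *flanked*: not buried itself,
    but both sequence neighbours (i−1 and i+1) are buried — by default each in
    at least one complex (``same_complex`` demands one complex burying both).
    """
    query = _positions_as_ints(positions)
    labels = {parse_position(p): str(p) for p in positions}
    union: set[int] = set()
    for region in interfaces:
        union |= set(region.positions)
    rows = []
    for q in query:
        if q in union:
            klass = "direct"
        else:
            if same_complex:
                flanked = any(
                    (q - 1) in region.positions and (q + 1) in region.positions
                    for region in interfaces
                )
            else:
                flanked = (q - 1) in union and (q + 1) in union
            klass = "flanked" if flanked else "none"
        rows.append(dict(position=labels[q], residue_number=q, participation=klass))
    return pd.DataFrame(rows)


def region_assignment(
    positions: list[str | int],
    region_map: dict[str, frozenset[int]] | None = None,
    inert_label: str = "Inert regions",
) -> pd.DataFrame:
    """Assign positions to functional regions (multi-membership allowed).

    Positions matching no region fall into the inert class.  Percentages are
    relative to the full query list, rounded to integer percent (half up).
    """
    if region_map is None:
        region_map = FUNCTIONAL_REGIONS
    query = _positions_as_ints(positions)
    labels = {parse_position(p): str(p) for p in positions}
    total = len(query)
    rows = []
    assigned: set[int] = set()
    for region, members in region_map.items():
        hit = [q for q in query if q in members]
        assigned |= set(hit)
        rows.append(
            dict(
                region=region,
                positions=",".join(labels[q] for q in sorted(hit)),
                n=len(hit),
                pct=percent_int(100.0 * len(hit) / total) if total else 0,
            )
        )
    inert = [q for q in query if q not in assigned]
    rows.append(
        dict(
            region=inert_label,
            positions=",".join(labels[q] for q in sorted(inert)),
            n=len(inert),
            pct=percent_int(100.0 * len(inert) / total) if total else 0,
        )
    )
    return pd.DataFrame(rows)
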