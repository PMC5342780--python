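"""PDB parsing, SASA engine, interface detection, clustering and overlap logic."""

import math

import numpy as np
import pytest

from dirpscan.structure import (
    Atom,
    ComplexStructure,
    InterfaceRegion,
    Residue,
    cluster_complexes,
    flanking_participation,
    interface_residues,
    kabsch_rmsd,
    match_positions,
    parse_structure,
    region_assignment,
    residue_sasa,
    round_half_down,
    shrake_rupley,
)
from dirpscan.synthetic import SyntheticSpec, synth_complex

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.040  1.00  0.00           C
ATOM      4  N   GLY A   2      10.291   4.348  -4.203  1.00  0.00           N
ATOM      5  CA  GLY A   2       9.501   3.287  -3.609  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
END
"""


class TestParseStructure:
    def test_minimal_two_residues(self):
        cx = parse_structure(MINIMAL_PDB, ras_chain="A", structure_id="mini")
        residues = cx.chains["A"]
        assert [r.name for r in residues] == ["ALA", "GLY"]
        assert [len(r.atoms) for r in residues] == [3, 2]
        assert residues[0].atoms[1].radius == pytest.approx(1.70)  # carbon

    def test_missing_chain_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            parse_structure(MINIMAL_PDB, ras_chain="B")

    def test_altloc_resolves_to_highest_occupancy(self):
        cx = parse_structure(ALTLOC_PDB, ras_chain="A")
        atoms = cx.chains["A"][0].atoms
        assert len(atoms) == 1
        assert atoms[0].coord[0] == pytest.approx(2.0)

    def test_pdb_round_trip(self):
        cx, _ = synth_complex(SyntheticSpec(seed=1))
        again = parse_structure(cx.to_pdb(), ras_chain="A", structure_id="SYNTH")
        for chain in cx.chains:
            a1 = [a.coord for a in (at for r in cx.chains[chain] for at in r.atoms)]
            a2 = [a.coord for a in (at for r in again.chains[chain] for at in r.atoms)]
            assert np.allclose(np.array(a1), np.array(a2), atol=1e-3)


def _sphere_analytic_cap(r1, r2, d, probe):
    """Exposed area of sphere 1 (radius r1+probe) occluded by sphere 2."""
    R1, R2 = r1 + probe, r2 + probe
    full = 4 * math.pi * R1**2
    if d >= R1 + R2:
        return full
    if d + R1 <= R2:
        return 0.0
    cos_theta = (R1**2 + d**2 - R2**2) / (2 * R1 * d)
    cap = 2 * math.pi * R1**2 * (1 - cos_theta)
    return full - cap


class TestShrakeRupley:
    def test_isolated_carbon_matches_sphere_area(self):
        area = shrake_rupley([Atom("C", "C", np.zeros(3), 1.7)])[0]
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact <= 0.01

    def test_distant_atoms_fully_exposed(self):
        a = Atom("C", "C", np.zeros(3), 1.7)
        b = Atom("C", "C", np.array([100.0, 0, 0]), 1.7)
        areas = shrake_rupley([a, b])
        assert np.allclose(areas, 4 * math.pi * 3.1**2, rtol=1e-6)

    def test_engulfed_atom_has_zero_area(self):
        inner = Atom("C", "C", np.zeros(3), 1.0)
        outer = Atom("S", "S", np.zeros(3), 8.0)
        assert shrake_rupley([inner, outer])[0] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_two_sphere_overlap_matches_analytic_formula(self, seed):
        rng = np.random.default_rng(seed)
        r1, r2 = rng.uniform(1.2, 2.0, size=2)
        d = float(rng.uniform(0.5, (r1 + r2 + 2 * 1.4) * 1.1))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        atoms = [
            Atom("X", "C", np.zeros(3), r1),
            Atom("Y", "C", d * direction, r2),
        ]
        area = shrake_rupley(atoms)[0]
        exact = _sphere_analytic_cap(r1, r2, d, 1.4)
        full = 4 * math.pi * (r1 + 1.4) ** 2
        assert abs(area - exact) <= 0.01 * full

    def test_cross_check_against_biopython_engine(self):
        # independent implementation comparison on the toy dimer
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley as BioSR
        import io

        cx, _ = synth_complex(SyntheticSpec(seed=3))
        structure = PDBParser(QUIET=True).get_structure("t", io.StringIO(cx.to_pdb()))
        BioSR(probe_radius=1.4, n_points=960).compute(structure[0], level="R")
        ours = residue_sasa(cx)
        for chain in structure[0]:
            for res in chain:
                mine = ours[(chain.id, res.id[1])]
                assert mine == pytest.approx(res.sasa, rel=0.02, abs=0.5)


def _shift(cx: ComplexStructure, transform) -> ComplexStructure:
    chains = {}
    for cid, residues in cx.chains.items():
        out = []
        for r in residues:
            atoms = tuple(
                Atom(a.name, a.element, transform(a.coord), a.radius) for a in r.atoms
            )
            out.append(Residue(r.name, r.number, atoms))
        chains[cid] = tuple(out)
    return ComplexStructure(cx.complex_id + "x", chains, cx.ras_chain_id)


class TestClustering:
    def test_identical_copies_form_one_group(self):
        cx, _ = synth_complex(SyntheticSpec(seed=4))
        groups = cluster_complexes([cx, _shift(cx, lambda c: c)])
        assert len(groups) == 1 and groups[0].max_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_superposes_to_zero(self):
        cx, _ = synth_complex(SyntheticSpec(seed=5))
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = _shift(cx, lambda c: rot @ c + np.array([5.0, -3.0, 8.0]))
        groups = cluster_complexes([cx, moved])
        assert len(groups) == 1 and groups[0].max_rmsd < 1e-8

    def test_noisy_copy_is_a_separate_group(self):
        cx, _ = synth_complex(SyntheticSpec(seed=6))
        rng = np.random.default_rng(0)
        noisy = _shift(cx, lambda c: c + rng.normal(0, 5.0, size=3))
        groups = cluster_complexes([cx, noisy])
        assert len(groups) == 2

    def test_kabsch_requires_three_atoms(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestInterfaceResidues:
    def test_designed_contacts_recovered_exactly(self):
        spec = SyntheticSpec(seed=7)
        cx, truth = synth_complex(spec)
        region = interface_residues(cx)
        assert sorted(region.positions) == sorted(truth.contacts)
        assert all(v > 1.0 for v in region.delta_sasa.values())

    def test_no_partner_means_empty_interface(self):
        cx, _ = synth_complex(SyntheticSpec(seed=8), separation=100.0)
        assert interface_residues(cx).positions == frozenset()

    def test_threshold_is_strict(self):
        spec = SyntheticSpec(seed=9)
        cx, _ = synth_complex(spec)
        deltas = interface_residues(cx, delta_threshold=0.0).delta_sasa
        boundary = max(deltas.values())
        at = interface_residues(cx, delta_threshold=boundary)
        assert all(v > boundary for v in at.delta_sasa.values())

    def test_partner_chain_also_buried(self):
        # binding hides surface on both sides of the toy dimer
        cx, _ = synth_complex(SyntheticSpec(seed=10))
        alone_b = residue_sasa(cx, ["B"])
        bound = residue_sasa(cx)
        lost = sum(alone_b[k] - bound[k] for k in alone_b)
        assert lost > 0


class TestOverlapLogic:
    def _regions(self):
        return [
            InterfaceRegion("C1", frozenset({10, 11, 12, 20})),
            InterfaceRegion("C2", frozenset({11, 30, 31})),
        ]

    def test_counts_and_ratios(self):
        table = match_positions(self._regions(), ["K11", "D30", "E99"])
        per_c = table.per_complex.set_index("complex_id")
        assert per_c.loc["C1", "n_matches"] == 1
        assert per_c.loc["C1", "ratio_pct"] == 25.0
        assert per_c.loc["C2", "n_matches"] == 2
        assert per_c.loc["C2", "ratio_pct"] == pytest.approx(66.7)

    def test_views_are_consistent(self):
        table = match_positions(self._regions(), ["K11", "D30", "E99"])
        assert table.per_complex["n_matches"].sum() == table.per_position["n_matches"].sum()

    def test_empty_positions(self):
        table = match_positions(self._regions(), [])
        assert (table.per_complex["n_matches"] == 0).all()

    def test_full_overlap_is_hundred_percent(self):
        region = InterfaceRegion("C", frozenset({1, 2, 3}))
        table = match_positions([region], [1, 2, 3])
        assert table.per_complex.loc[0, "ratio_pct"] == 100.0

    def test_flanked_requires_both_neighbors(self):
        regions = [InterfaceRegion("C", frozenset({34, 36}))]
        frame = flanking_participation(regions, ["T35", "G33", "I36"]).set_index("position")
        assert frame.loc["T35", "participation"] == "flanked"
        assert frame.loc["I36", "participation"] == "direct"
        assert frame.loc["G33", "participation"] == "none"  # 32 not buried

    def test_union_vs_same_complex_rule(self):
        regions = [
            InterfaceRegion("C1", frozenset({27})),
            InterfaceRegion("C2", frozenset({29})),
        ]
        union = flanking_participation(regions, ["F28"]).loc[0, "participation"]
        strict = flanking_participation(regions, ["F28"], same_complex=True).loc[0, "participation"]
        assert union == "flanked" and strict == "none"

    def test_terminal_position_never_flanked(self):
        regions = [InterfaceRegion("C", frozenset({2}))]
        frame = flanking_participation(regions, ["M1"])
        assert frame.loc[0, "participation"] == "none"

    def test_region_assignment_multi_membership_and_inert(self):
        region_map = {"R1": frozenset({1, 2, 3}), "R2": frozenset({3, 4})}
        frame = region_assignment(["A3", "G4", "K9"], region_map, inert_label="inert")
        by = frame.set_index("region")
        assert by.loc["R1", "positions"] == "A3"
        assert by.loc["R2", "positions"] == "A3,G4"
        assert by.loc["inert", "positions"] == "K9"
        assert by.loc["R2", "pct"] == 67

    def test_half_down_rounding(self):
        assert round_half_down(43.75, 1) == 43.7
        assert round_half_down(38.095, 1) == 38.1
        assert round_half_down(36.36, 1) == 36.4
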