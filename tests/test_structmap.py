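"""Structure parsing, sequence mapping, SASA and region classification."""

import math

import numpy as np
import pytest

from conftest import chain_structure, make_structure
from patchnet import structmap
from patchnet.structmap import (
    MAX_ASA_TIEN_2013,
    Atom,
    MutationRecord,
    Residue,
    Structure,
    StructureParseError,
    align_sequence_to_structure,
    classify_regions,
    compute_sasa,
    find_interface_residues,
    map_mutations_to_structure,
    parse_structure,
    write_pdb,
)
from patchnet.synthcohort import generate_structure

PDB_ONE_ATOM = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)

PDB_WATER_ONLY = (
    "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
    "END\n"
)


class TestParseStructure:
    def test_single_atom_record(self):
        s = parse_structure(PDB_ONE_ATOM)
        assert len(s) == 1
        assert s.residues[0].resname == "ALA"
        assert s.residues[0].atoms[0].coord == (1.0, 2.0, 3.0)

    def test_waters_and_hetatm_ignored(self):
        assert len(parse_structure(PDB_WATER_ONLY)) == 0

    def test_malformed_atom_line_reports_line_number(self):
        bad = PDB_ONE_ATOM.replace("1.000", "1.0xx", 1)
        with pytest.raises(StructureParseError, match="line 1"):
            parse_structure(bad)

    def test_synthetic_structure_roundtrips_through_pdb(self):
        original = generate_structure(60, seed=5, protein="G1")
        parsed = parse_structure(write_pdb(original), "G1")
        assert len(parsed) == len(original)
        for r0, r1 in zip(original.residues, parsed.residues):
            assert r0.key == r1.key and r0.resname == r1.resname
            np.testing.assert_allclose(r0.coords, r1.coords, atol=1.5e-3)


class TestSequenceMapping:
    def test_identical_sequence_with_offset_numbering(self):
        seq = "ACDEFGHIKL"
        resnames = [structmap.ONE_TO_THREE[a] for a in seq]
        s = make_structure(
            [(i * 3.8, 0, 0) for i in range(10)], resnames=resnames, start=10
        )
        m = align_sequence_to_structure(seq, s, "A")
        assert m.identity == 1.0
        assert m.position_to_key == {i: ("A", str(i + 9)) for i in range(1, 11)}

    def test_structure_fragment_maps_only_covered_positions(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" + "YWVTSRQPNMLKIHGFEDCA"  # no repeats
        fragment = seq[4:20]  # canonical positions 5..20
        resnames = [structmap.ONE_TO_THREE[a] for a in fragment]
        s = make_structure(
            [(i * 3.8, 0, 0) for i in range(len(fragment))],
            resnames=resnames,
            start=5,
        )
        m = align_sequence_to_structure(seq, s, "A")
        assert set(m.position_to_key) == set(range(5, 21))

    def test_internal_deletion_columns_absent(self):
        # independent dynamic-programming expectation: a 3-residue internal
        # deletion leaves positions 6..8 unmapped, all others aligned
        seq = "ACDEFGHIKLMNPQR"
        deleted = seq[:5] + seq[8:]
        resnames = [structmap.ONE_TO_THREE[a] for a in deleted]
        s = make_structure(
            [(i * 3.8, 0, 0) for i in range(len(deleted))], resnames=resnames
        )
        m = align_sequence_to_structure(seq, s, "A")
        assert set(m.position_to_key) == set(range(1, 16)) - {6, 7, 8}

    def test_low_identity_mapping_rejected(self):
        seq = "A" * 30
        s = make_structure(
            [(i * 3.8, 0, 0) for i in range(30)], resnames=["LEU"] * 30
        )
        m = align_sequence_to_structure(seq, s, "A")
        assert len(m) == 0 and m.identity < 0.9

    def test_empty_sequence_rejected(self):
        s = chain_structure(3)
        with pytest.raises(ValueError):
            align_sequence_to_structure("", s, "A")


class TestSasa:
    def test_isolated_atom_matches_closed_form(self):
        s = make_structure([(0, 0, 0)])
        sasa = compute_sasa(s)
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert sasa[("A", "1")] == pytest.approx(expected, rel=1e-9)

    def test_two_distant_atoms_do_not_occlude(self):
        s = make_structure([(0, 0, 0), (50, 0, 0)])
        sasa = compute_sasa(s)
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert sasa[("A", "1")] == pytest.approx(expected, rel=1e-9)
        assert sasa[("A", "2")] == pytest.approx(expected, rel=1e-9)

    def test_refinement_oracle_on_toy_peptide(self):
        # 5-residue peptide: coarse run within 5% of a 10000-point rerun
        s = chain_structure(5)
        coarse = compute_sasa(s, n_sphere_points=960)
        fine = compute_sasa(s, n_sphere_points=10000)
        for key in coarse:
            assert coarse[key] == pytest.approx(fine[key], rel=0.05)

    def test_against_independent_shrake_rupley(self):
        # cross-check against Bio.PDB's independent implementation
        from Bio.PDB.SASA import ShrakeRupley

        structure = generate_structure(55, seed=3, protein="X")
        ours = compute_sasa(structure, n_sphere_points=960)

        from Bio.PDB import PDBParser
        import io

        bio = PDBParser(QUIET=True).get_structure(
            "X", io.StringIO(write_pdb(structure))
        )
        sr = ShrakeRupley(probe_radius=1.4, n_points=960)
        sr.compute(bio, level="R")
        for chain in bio[0]:
            for res in chain:
                key = ("A", str(res.get_id()[1]))
                assert ours[key] == pytest.approx(res.sasa, rel=0.07, abs=2.0)

    def test_occlusion_never_increases_sasa(self):
        base = chain_structure(6)
        sasa0 = compute_sasa(base, n_sphere_points=960)
        occluded = make_structure(
            [(i * 3.8, 0, 0) for i in range(6)] + [(1.9, 2.5, 0.0)]
        )
        sasa1 = compute_sasa(occluded, n_sphere_points=960)
        for i in range(1, 7):
            assert sasa1[("A", str(i))] <= sasa0[("A", str(i))] + 1e-9

    def test_empty_structure_invalid(self):
        with pytest.raises(ValueError):
            compute_sasa(Structure("empty", []))


def _uniform_sasa_structure(n, rsa_value):
    """n ALA residues whose fake SASA dict gives the requested RSA."""
    s = make_structure([(i * 10.0, 0, 0) for i in range(n)])
    sasa = {r.key: rsa_value * MAX_ASA_TIEN_2013["ALA"] for r in s.residues}
    return s, sasa


class TestRegions:
    def test_rsa_boundary_is_surface(self):
        s, sasa = _uniform_sasa_structure(60, 0.05)
        labels = classify_regions(s, sasa)
        assert all(l.label == "surface" for l in labels.values())

    def test_zero_rsa_is_core(self):
        s, sasa = _uniform_sasa_structure(60, 0.0)
        labels = classify_regions(s, sasa)
        assert all(l.label == "core" for l in labels.values())

    def test_interface_overrides_surface(self):
        s, sasa = _uniform_sasa_structure(60, 0.8)
        labels = classify_regions(s, sasa, interface_residues={("A", "1")})
        assert labels[("A", "1")].label == "interface"
        assert labels[("A", "2")].label == "surface"

    def test_short_structures_skipped(self):
        s, sasa = _uniform_sasa_structure(50, 0.5)
        assert classify_regions(s, sasa) == {}

    def test_partition_is_exhaustive_and_exclusive(self):
        s, sasa = _uniform_sasa_structure(70, 0.5)
        for i in range(0, 20):
            sasa[("A", str(i + 1))] = 0.0
        labels = classify_regions(s, sasa, interface_residues={("A", "30")})
        counts = {"core": 0, "surface": 0, "interface": 0}
        for l in labels.values():
            counts[l.label] += 1
        assert sum(counts.values()) == len(labels) == 70

    def test_missing_residue_type_raises(self):
        s, sasa = _uniform_sasa_structure(60, 0.5)
        with pytest.raises(KeyError):
            classify_regions(s, sasa, max_asa_table={"GLY": 104.0})


class TestInterfaceResidues:
    def _dimer(self, gap):
        residues = [
            Residue("A", "1", "ALA", (Atom("CA", "C", (0.0, 0.0, 0.0)),)),
            Residue("A", "2", "ALA", (Atom("CA", "C", (3.8, 0.0, 0.0)),)),
            Residue("B", "1", "ALA", (Atom("CA", "C", (0.0, gap, 0.0)),)),
            Residue("B", "2", "ALA", (Atom("CA", "C", (3.8, gap + 3.0, 0.0)),)),
        ]
        return Structure("dimer", residues)

    def test_distant_chains_have_no_interface(self):
        out = find_interface_residues(self._dimer(6.2), "A", "B")
        assert out == {"A": set(), "B": set()}

    def test_single_contact_pair(self):
        out = find_interface_residues(self._dimer(4.9), "A", "B")
        assert out["A"] == {("A", "1")} and out["B"] == {("B", "1")}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        coords_a = rng.uniform(0, 15, size=(12, 3))
        coords_b = rng.uniform(5, 20, size=(12, 3))
        residues = [
            Residue("A", str(i + 1), "ALA", (Atom("CA", "C", tuple(c)),))
            for i, c in enumerate(coords_a)
        ] + [
            Residue("B", str(i + 1), "ALA", (Atom("CA", "C", tuple(c)),))
            for i, c in enumerate(coords_b)
        ]
        s = Structure("dimer", residues)
        out = find_interface_residues(s, "A", "B", cutoff=5.0)
        expect_a, expect_b = set(), set()
        for i, ca in enumerate(coords_a):
            for j, cb in enumerate(coords_b):
                if np.linalg.norm(ca - cb) < 5.0:
                    expect_a.add(("A", str(i + 1)))
                    expect_b.add(("B", str(j + 1)))
        assert out["A"] == expect_a and out["B"] == expect_b

    def test_symmetry(self):
        for gap in (4.0, 8.0):
            ab = find_interface_residues(self._dimer(gap), "A", "B")
            ba = find_interface_residues(self._dimer(gap), "B", "A")
            assert bool(ab["A"]) == bool(ba["B"]) == bool(ab["B"])

    def test_missing_chain_rejected(self):
        with pytest.raises(ValueError):
            find_interface_residues(self._dimer(5.0), "A", "Z")


class TestMutationMapping:
    def _setup(self):
        seq = "ACDEFGHIKL"
        resnames = [structmap.ONE_TO_THREE[a] for a in seq]
        s = make_structure(
            [(i * 3.8, 0, 0) for i in range(10)], resnames=resnames,
            structure_id="S1",
        )
        mapping = align_sequence_to_structure(seq, s, "A", protein="PROT")
        return s, mapping

    def test_unmapped_and_mismatch_and_conservation(self):
        s, mapping = self._setup()
        muts = [
            MutationRecord("p1", "PROT", 3, "D", "N", "missense"),
            MutationRecord("p1", "PROT", 99, "A", "V", "missense"),
            MutationRecord("p2", "PROT", 4, "W", "R", "missense"),  # real ref is E
            MutationRecord("p2", "OTHER", 1, "A", "T", "missense"),
        ]
        placed = map_mutations_to_structure(muts, [mapping], {"S1": {}}, {"S1": s})
        statuses = [p.status for p in placed]
        assert statuses == ["mapped", "unmapped", "ref-mismatch", "unmapped"]
        assert len(placed) == len(muts)

    def test_primary_placement_prefers_longest_structure(self):
        seq = "ACDEFGHIKL"
        resnames = [structmap.ONE_TO_THREE[a] for a in seq]
        full = make_structure(
            [(i * 3.8, 0, 0) for i in range(10)], resnames=resnames,
            structure_id="LONG",
        )
        frag = make_structure(
            [(i * 3.8, 0, 0) for i in range(5)], resnames=resnames[:5],
            structure_id="SHORT",
        )
        mappings = [
            align_sequence_to_structure(seq, full, "A", protein="PROT"),
            align_sequence_to_structure(seq[:5], frag, "A", protein="PROT"),
        ]
        muts = [MutationRecord("p1", "PROT", 2, "C", "Y", "missense")]
        placed = map_mutations_to_structure(muts, mappings, {})
        assert placed[0].primary[0] == "LONG"
        assert len(placed[0].placements) == 2
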