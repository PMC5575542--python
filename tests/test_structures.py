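import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import brute_force_min_rmsd
from paleoenrich.containers import ProteinAlignment
from paleoenrich.regions import REGION_LABELS, RegionConfig, RegionMap, build_region_map
from paleoenrich.simulate import gen_toy_complex, gen_toy_dimer
from paleoenrich.structures import (
    GeometryError,
    MappingError,
    StructureModel,
    cross_model_interface,
    extract_dimer,
    interface_residues,
    map_residues_to_alignment,
    near_set,
    ordinal_pairing,
    read_structure,
    subdomain_by_nearest_ca,
    superimpose,
    write_pdb,
)


def _rigid_copy(model, seed=0, angle=None):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix() if angle is None else (
        Rotation.from_euler("z", angle, degrees=True).as_matrix())
    t = rng.normal(scale=10, size=3)
    moved = model.copy()
    for residues in moved.chains.values():
        for r in residues:
            for a in r.atoms:
                a.xyz = R @ a.xyz + t
    return moved, R, t


class TestReadWrite:
    def test_round_trip_preserves_chains_and_coords(self, tmp_path):
        m = gen_toy_dimer(6, [(2, 2)])
        path = tmp_path / "toy.pdb"
        write_pdb(m, path)
        back = read_structure(path)
        assert set(back.chain_ids) == {"A", "B"}
        assert len(back.chains["A"]) == 6
        orig = m.residue(("A", 2)).atom("CA").xyz
        again = back.residue(("A", 2)).atom("CA").xyz
        assert np.abs(orig - again).max() < 1e-3  # PDB precision

    def test_waters_and_ligands_dropped(self, tmp_path):
        pdb = tmp_path / "mixed.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "HETATM    4  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O\n"
            "HETATM    5 C1   LIG A 102      25.000  25.000  25.000  1.00  0.00           C\n"
            "END\n"
        )
        m = read_structure(pdb)
        assert len(m.chains["A"]) == 3
        assert all(r.name in ("ALA", "GLY") for r in m.chains["A"])

    def test_modified_residue_renamed_to_parent(self, tmp_path):
        pdb = tmp_path / "mod.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  CA  KCX A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  CA  MSE A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        m = read_structure(pdb)
        names = [r.name for r in m.chains["A"]]
        assert names == ["ALA", "LYS", "MET"]

    def test_unparseable_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("not a structure\n")
        with pytest.raises(Exception):
            read_structure(bad)


class TestExtractDimer:
    def test_four_chain_complex_reduced_to_two(self):
        dimer = gen_toy_dimer(5, [])
        complex_ = gen_toy_complex(dimer, {"C": [("A", 1)], "S": [("B", 2)]})
        out = extract_dimer(complex_, ("A", "B"))
        assert set(out.chain_ids) == {"A", "B"}

    def test_already_dimer_unchanged(self):
        m = gen_toy_dimer(5, [])
        out = extract_dimer(m, ("A", "B"))
        assert {len(v) for v in out.chains.values()} == {5}

    def test_missing_chain_rejected(self):
        m = gen_toy_dimer(5, [])
        with pytest.raises(ValueError):
            extract_dimer(m, ("A", "Z"))


class TestSuperimpose:
    def test_identity_superposition_has_zero_rmsd(self):
        m = gen_toy_dimer(6, [(2, 2)])
        sup = superimpose(m, m, ordinal_pairing(m, m))
        assert sup.rmsd < 1e-9
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self):
        m = gen_toy_dimer(6, [])
        moved, R, t = _rigid_copy(m, angle=90)
        sup = superimpose(moved, m, ordinal_pairing(moved, m))
        assert sup.rmsd < 1e-9
        # transform must invert the applied motion
        assert np.allclose(sup.rotation @ R, np.eye(3), atol=1e-9)

    def test_rmsd_matches_brute_force_minimum(self, rng):
        pts = rng.normal(scale=5, size=(4, 3))
        noisy = pts + rng.normal(scale=0.4, size=(4, 3))
        chains_a = {"A": [_point_residue("A", i + 1, p) for i, p in enumerate(pts)]}
        chains_b = {"A": [_point_residue("A", i + 1, p) for i, p in enumerate(noisy)]}
        sa, sb = StructureModel(chains_a), StructureModel(chains_b)
        sup = superimpose(sb, sa, ordinal_pairing(sb, sa, ("A",), ("A",)))
        expected = brute_force_min_rmsd(noisy, pts)
        assert sup.rmsd == pytest.approx(expected, abs=1e-6)

    def test_too_few_or_collinear_rejected(self):
        line = [_point_residue("A", i + 1, np.array([i, 0.0, 0.0])) for i in range(4)]
        s = StructureModel({"A": line})
        with pytest.raises(GeometryError):
            superimpose(s, s, ordinal_pairing(s, s, ("A",), ("A",)))
        two = StructureModel({"A": line[:2]})
        with pytest.raises(GeometryError):
            superimpose(two, two, [(("A", 1), ("A", 1)), (("A", 2), ("A", 2))])


def _point_residue(chain, idx, xyz):
    from paleoenrich.structures import Atom, Residue

    return Residue(chain, idx, "GLY", [Atom("CA", "C", np.asarray(xyz, float))])


class TestInterfaceRules:
    def test_strict_cutoff_boundary(self):
        """A contact constructed at 4.9 A is detected at the 5 A cutoff; the
        same geometry is invisible at a 4.8 A cutoff (strict inequality)."""
        m = gen_toy_dimer(8, [(4, 4)], cutoff=5.0)
        assert interface_residues(m, m.residue_keys("A"), m.residue_keys("B"), 5.0) == {("A", 4)}
        assert interface_residues(m, m.residue_keys("A"), m.residue_keys("B"), 4.85) == set()

    def test_contact_just_outside_not_detected(self):
        # constructed for a 5.2 cutoff => contact distance 5.1 > 5.0
        m = gen_toy_dimer(8, [(4, 4)], cutoff=5.2)
        assert interface_residues(m, m.residue_keys("A"), m.residue_keys("B"), 5.0) == set()

    def test_overlapping_sides_rejected(self):
        m = gen_toy_dimer(4, [])
        with pytest.raises(ValueError):
            interface_residues(m, m.residue_keys("A"), m.residue_keys("A"), 5.0)

    def test_cutoff_monotonicity(self):
        m = gen_toy_dimer(10, [(2, 2), (6, 6)])
        previous = set()
        for cutoff in (1.0, 4.0, 4.95, 6.0, 12.0, 20.0):
            current = interface_residues(m, m.residue_keys("A"), m.residue_keys("B"), cutoff)
            assert previous <= current
            previous = current

    def test_near_set_basics(self):
        m = gen_toy_dimer(10, [])
        core = {("A", 5)}
        near = near_set(m, core, 5.0)
        assert ("A", 5) not in near
        assert ("A", 4) in near and ("A", 6) in near  # 4.5 A spacing < 5
        assert near_set(m, core, 1e-9) == set()
        with pytest.raises(ValueError):
            near_set(m, set(), 5.0)


class TestCrossModelInterface:
    def test_identical_query_reproduces_reference_contacts(self):
        dimer = gen_toy_dimer(10, [])
        complex_ = gen_toy_complex(dimer, {"C": [("A", 4), ("B", 7)]})
        got = cross_model_interface(
            dimer, complex_, {"C"}, ordinal_pairing(dimer, complex_), 5.0
        )
        assert got == {("A", 4), ("B", 7)}

    def test_empty_partner_chain_set_gives_empty(self):
        dimer = gen_toy_dimer(6, [])
        complex_ = gen_toy_complex(dimer, {"C": [("A", 2)]})
        assert cross_model_interface(dimer, complex_, set(),
                                     ordinal_pairing(dimer, complex_), 5.0) == set()

    def test_rigidly_moved_query_gives_same_answer(self):
        dimer = gen_toy_dimer(10, [])
        complex_ = gen_toy_complex(dimer, {"C": [("A", 3)]})
        moved, _, _ = _rigid_copy(dimer, seed=5)
        got = cross_model_interface(moved, complex_, {"C"},
                                    ordinal_pairing(moved, complex_), 5.0)
        assert got == {("A", 3)}


class TestSubdomainTransfer:
    def test_self_mapping(self):
        m = gen_toy_dimer(8, [])
        sub = {("A", 2), ("A", 5), ("B", 7)}
        got = subdomain_by_nearest_ca(m, m, sub, ordinal_pairing(m, m))
        assert got == sub

    def test_translation_invariant(self):
        m = gen_toy_dimer(8, [])
        moved, _, _ = _rigid_copy(m, seed=2)
        sub = {("A", 3), ("B", 6)}
        got = subdomain_by_nearest_ca(moved, m, sub, ordinal_pairing(moved, m))
        assert got == sub

    def test_equidistant_tie_takes_lower_key(self):
        # query residues 3 and 4 are exactly equidistant from reference
        # residue 4 (at the midpoint); the lower residue index must win
        coords = {
            1: [0.0, 0.0, 0.0],
            2: [10.0, 0.0, 0.0],
            3: [0.0, 10.0, 0.0],
            4: [10.0, 10.0, 0.0],
        }
        q = StructureModel({"A": [_point_residue("A", i, c) for i, c in coords.items()]})
        ref = q.copy()
        ref.residue(("A", 4)).atoms[0].xyz = np.array([5.0, 10.0, 0.0])
        # identity pairing on residues 1-3 keeps the superposition trivial
        pairing = [(("A", i), ("A", i)) for i in (1, 2, 3)]
        got = subdomain_by_nearest_ca(q, ref, {("A", 4)}, pairing)
        assert got == {("A", 3)}


class TestAlignmentMapping:
    def test_forced_mapping(self):
        mapping, mismatches = map_residues_to_alignment("ACDE", "AC-DE")
        assert mapping == {1: 0, 2: 1, 3: 3, 4: 4}
        assert mismatches == []

    def test_all_gap_row_rejected(self):
        with pytest.raises(MappingError):
            map_residues_to_alignment("ACDE", "----")

    def test_mismatch_under_tolerance_flagged(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        row = "ACDEFGHIKLMNPQRSTVWW"  # one mismatch = 5%
        mapping, mismatches = map_residues_to_alignment(seq, row, 0.05)
        assert mismatches == [20]
        with pytest.raises(MappingError):
            map_residues_to_alignment(seq, row, 0.01)


class TestRegionMapConstruction:
    @pytest.fixture()
    def built(self, fixture_bundle):
        d = fixture_bundle["dir"]
        aln = ProteinAlignment.from_fasta(d / "alignment.fasta")
        sub = fixture_bundle["subdomains"]
        rc = RegionConfig(
            barrel_strand_residues=sub["barrel_strands"],
            loop6_residues=sub["loop6"],
            n_terminal_residues=sub["N_terminal"],
            c_terminal_residues=sub["C_terminal"],
        )
        structures = {
            name: read_structure(d / fixture_bundle["files"][name])
            for name in ("query_dimer", "form1_reference", "form3_reference",
                         "subdomain_reference")
        }
        return d, aln, rc, structures, fixture_bundle

    def _truth_in_columns(self, d, aln, reference_taxon):
        cmap, _ = map_residues_to_alignment(
            aln.ungapped(reference_taxon), aln.sequence(reference_taxon)
        )
        truth = {}
        for line in (d / "region_truth_residues.tsv").read_text().splitlines()[1:]:
            label, residues = line.split("\t")
            truth[label] = {cmap[int(x)] for x in residues.split(",") if x}
        return truth

    def test_matches_fixture_truth_exactly(self, built):
        d, aln, rc, structures, manifest = built
        rmap = build_region_map(
            rc, structures["query_dimer"], structures["form1_reference"],
            structures["form3_reference"], structures["subdomain_reference"],
            aln, manifest["reference_taxon"],
        )
        truth = self._truth_in_columns(d, aln, manifest["reference_taxon"])
        for label in REGION_LABELS:
            assert set(rmap[label]) == truth[label], label

    def test_rigid_motion_invariance_of_all_regions(self, built):
        d, aln, rc, structures, manifest = built
        base = build_region_map(
            rc, structures["query_dimer"], structures["form1_reference"],
            structures["form3_reference"], structures["subdomain_reference"],
            aln, manifest["reference_taxon"],
        )
        moved, _, _ = _rigid_copy(structures["query_dimer"], seed=11)
        rotated = build_region_map(
            rc, moved, structures["form1_reference"],
            structures["form3_reference"], structures["subdomain_reference"],
            aln, manifest["reference_taxon"],
        )
        for label in REGION_LABELS:
            assert base[label] == rotated[label], label

    def test_empty_subdomain_lists_leave_other_regions(self, built):
        d, aln, rc, structures, manifest = built
        rc_empty = RegionConfig()
        rmap = build_region_map(
            rc_empty, structures["query_dimer"], structures["form1_reference"],
            structures["form3_reference"], structures["subdomain_reference"],
            aln, manifest["reference_taxon"],
        )
        assert rmap["barrel_strands"] == frozenset()
        assert rmap["near_barrel"] == frozenset()
        assert rmap["dimer_interface"]  # geometric regions unaffected

    def test_symmetric_homodimer_maps_both_chains_to_same_columns(self):
        dimer = gen_toy_dimer(10, [(3, 3), (7, 7)], sequence="ACDEFGHIKL")
        a = interface_residues(dimer, dimer.residue_keys("A"), dimer.residue_keys("B"), 5.0)
        b = interface_residues(dimer, dimer.residue_keys("B"), dimer.residue_keys("A"), 5.0)
        assert {i for _, i in a} == {i for _, i in b}

    def test_serialization_round_trip(self, built, tmp_path):
        d, aln, rc, structures, manifest = built
        rmap = build_region_map(
            rc, structures["query_dimer"], structures["form1_reference"],
            structures["form3_reference"], structures["subdomain_reference"],
            aln, manifest["reference_taxon"],
        )
        path = tmp_path / "rm.json"
        rmap.to_json(path)
        back = RegionMap.from_json(path)
        assert all(back[label] == rmap[label] for label in REGION_LABELS)
        tsv = tmp_path / "rm.tsv"
        rmap.to_tsv(tsv, aln.length)
        lines = tsv.read_text().splitlines()
        assert sum(1 for l in lines if not l.startswith("#")) == aln.length + 1
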