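import numpy as np
import pytest

from glycurate.model import (AtomRecord, DuplicateResidueError, LinkRecord,
                             ResidueRecord, StructureModel, UndefinedDistanceError,
                             min_symmetry_distance, read_structure, write_structure)
from oracles import brute_force_symmetry_min


def small_model():
    asn = ResidueRecord("A", 24, "ASN", [
        AtomRecord("N", "N", [10, 10, 10]), AtomRecord("CA", "C", [11.4, 10, 10]),
        AtomRecord("CB", "C", [12, 11.2, 10]), AtomRecord("CG", "C", [13.4, 11.2, 10]),
        AtomRecord("OD1", "O", [14, 10.2, 10]), AtomRecord("ND2", "N", [14.1, 12.3, 10]),
        AtomRecord("C", "C", [11.9, 9, 9]), AtomRecord("O", "O", [11.3, 8, 9])])
    nag = ResidueRecord("A", 401, "NAG", [AtomRecord("C1", "C", [15.2, 13.0, 10.4], b=30.0)])
    return StructureModel(
        residues=[asn, nag], cell=(40, 40, 40, 90, 90, 90), resolution=2.0,
        links=[LinkRecord(("A", 24, "", "ND2"), ("A", 401, "", "C1"), 1.44)])


MINIMAL_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1
ATOM      1  CA  GLY A   1      10.000  11.000  12.000  1.00 15.00           C
END
"""


def test_minimal_pdb_parses_with_identity_symmetry(tmp_path):
    path = tmp_path / "m.pdb"
    path.write_text(MINIMAL_PDB)
    m = read_structure(str(path))
    assert len(m.residues) == 1
    assert m.residues[0].comp_id == "GLY"
    assert len(m.sym_ops) == 1
    np.testing.assert_allclose(m.sym_ops[0][0], np.eye(3))


def test_link_line_maps_to_link_record(tmp_path):
    text = ("CRYST1   40.000   40.000   40.000  90.00  90.00  90.00 P 1\n"
            "LINK         ND2 ASN A  24                 C1  NAG A 401\n"
            "ATOM      1  ND2 ASN A  24      10.000  10.000  10.000  1.00 20.00           N\n"
            "HETATM    2  C1  NAG A 401      11.400  10.000  10.000  1.00 30.00           C\n"
            "END\n")
    path = tmp_path / "l.pdb"
    path.write_text(text)
    m = read_structure(str(path))
    assert len(m.links) == 1
    assert m.links[0].atom_a == ("A", 24, "", "ND2")
    assert m.links[0].atom_b == ("A", 401, "", "C1")


@pytest.mark.parametrize("fmt", ["pdb", "mmcif"])
def test_round_trip_is_lossless(tmp_path, fmt):
    m = small_model()
    ext = ".pdb" if fmt == "pdb" else ".cif"
    p1 = tmp_path / f"a{ext}"
    write_structure(m, str(p1), fmt)
    m2 = read_structure(str(p1), fmt)
    assert len(m2.residues) == len(m.residues)
    assert len(m2.links) == len(m.links)
    assert m2.cell == pytest.approx(m.cell)
    for r, r2 in zip(m.residues, m2.residues):
        assert r.key == r2.key and r.comp_id == r2.comp_id
        for a, a2 in zip(r.atoms, r2.atoms):
            assert a.name == a2.name
            np.testing.assert_allclose(a.pos, a2.pos, atol=1e-3)
            assert a.b == pytest.approx(a2.b, abs=1e-2)
            assert a.occ == pytest.approx(a2.occ, abs=1e-2)
    # second round trip is exactly stable
    p2 = tmp_path / f"b{ext}"
    write_structure(m2, str(p2), fmt)
    m3 = read_structure(str(p2), fmt)
    for r2, r3 in zip(m2.residues, m3.residues):
        for a2, a3 in zip(r2.atoms, r3.atoms):
            np.testing.assert_allclose(a2.pos, a3.pos, atol=1e-3)


def test_glycosite_fixture_round_trips(tmp_path, glycosite_bundle):
    truth, _, _ = glycosite_bundle
    path = tmp_path / "site.pdb"
    write_structure(truth, str(path))
    again = read_structure(str(path))
    assert len(again.residues) == len(truth.residues)
    assert len(again.links) == len(truth.links)
    for r, r2 in zip(truth.residues, again.residues):
        np.testing.assert_allclose(r.positions(), r2.positions(), atol=1e-3)


def test_duplicate_residue_ids_refuse_to_write(tmp_path):
    m = small_model()
    dup = m.residues[0].copy()
    m.residues.append(dup)
    with pytest.raises(DuplicateResidueError, match="24"):
        write_structure(m, str(tmp_path / "dup.pdb"))


def test_empty_model_writes_header_only(tmp_path):
    m = StructureModel(cell=(10, 10, 10, 90, 90, 90))
    path = tmp_path / "empty.pdb"
    write_structure(m, str(path))
    m2 = read_structure(str(path))
    assert m2.residues == []


def test_unknown_format_token_rejected(tmp_path):
    with pytest.raises(ValueError, match="format"):
        read_structure(str(tmp_path / "x.pdb"), fmt="xyz")


def test_unparseable_file_raises_format_error(tmp_path):
    path = tmp_path / "junk.cif"
    path.write_text("this is not a structure\n")
    with pytest.raises(ValueError):
        read_structure(str(path), fmt="mmcif")


class TestMinSymmetryDistance:
    def test_direct_distance_p1(self):
        a = ResidueRecord("A", 1, "HOH", [AtomRecord("O", "O", [5, 5, 5])])
        b = ResidueRecord("A", 2, "HOH", [AtomRecord("O", "O", [5, 5, 8])])
        m = StructureModel(residues=[a, b], cell=(50, 50, 50, 90, 90, 90))
        d, (pa, ta) = min_symmetry_distance(m, a.atoms, b.atoms)
        assert d == pytest.approx(3.0)

    def test_periodic_image_across_cell_edge(self):
        a = ResidueRecord("A", 1, "HOH", [AtomRecord("O", "O", [0.5, 0, 0])])
        b = ResidueRecord("A", 2, "HOH", [AtomRecord("O", "O", [9.5, 0, 0])])
        m = StructureModel(residues=[a, b], cell=(10, 10, 10, 90, 90, 90))
        d, _ = min_symmetry_distance(m, a.atoms, b.atoms)
        assert d == pytest.approx(1.0)

    def test_screw_operator_matches_brute_force(self):
        # P21-like operator: -x, y+1/2, -z
        op = (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0]))
        rng = np.random.default_rng(5)
        a = ResidueRecord("A", 1, "HOH",
                          [AtomRecord("O", "O", rng.uniform(0, 12, 3)) for _ in range(4)])
        b = ResidueRecord("A", 2, "HOH",
                          [AtomRecord("O", "O", rng.uniform(0, 12, 3)) for _ in range(5)])
        m = StructureModel(residues=[a, b], cell=(12, 14, 16, 90, 90, 90), sym_ops=[op])
        d, _ = min_symmetry_distance(m, a.atoms, b.atoms)
        assert d == pytest.approx(brute_force_symmetry_min(m, a.atoms, b.atoms), abs=1e-9)

    def test_randomized_models_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            atoms_a = [AtomRecord("O", "O", rng.uniform(0, 15, 3)) for _ in range(3)]
            atoms_b = [AtomRecord("O", "O", rng.uniform(0, 15, 3)) for _ in range(3)]
            a = ResidueRecord("A", 1, "HOH", atoms_a)
            b = ResidueRecord("A", 2, "HOH", atoms_b)
            op = (np.diag([-1.0, -1.0, 1.0]), np.array([0.5, 0.0, 0.5]))
            m = StructureModel(residues=[a, b], cell=(15, 15, 18, 90, 90, 90), sym_ops=[op])
            d, _ = min_symmetry_distance(m, a.atoms, b.atoms)
            assert d == pytest.approx(brute_force_symmetry_min(m, a.atoms, b.atoms), abs=1e-9)

    def test_symmetric_in_probe_and_target(self):
        rng = np.random.default_rng(3)
        a = ResidueRecord("A", 1, "HOH", [AtomRecord("O", "O", rng.uniform(0, 10, 3))])
        b = ResidueRecord("A", 2, "HOH", [AtomRecord("O", "O", rng.uniform(0, 10, 3))])
        m = StructureModel(residues=[a, b], cell=(10, 12, 14, 90, 90, 90))
        d1, _ = min_symmetry_distance(m, a.atoms, b.atoms)
        d2, _ = min_symmetry_distance(m, b.atoms, a.atoms)
        assert d1 == pytest.approx(d2)

    def test_empty_set_is_undefined_not_numeric(self):
        a = ResidueRecord("A", 1, "HOH", [AtomRecord("O", "O", [1, 1, 1])])
        m = StructureModel(residues=[a], cell=(10, 10, 10, 90, 90, 90))
        with pytest.raises(UndefinedDistanceError):
            min_symmetry_distance(m, [], a.atoms)

    def test_identity_self_pairs_excluded(self):
        a = ResidueRecord("A", 1, "HOH", [AtomRecord("O", "O", [5, 5, 5])])
        m = StructureModel(residues=[a], cell=(10, 10, 10, 90, 90, 90))
        d, _ = min_symmetry_distance(m, a.atoms, a.atoms)
        assert d == pytest.approx(10.0)  # nearest lattice image, not itself


def test_flat_b_detected_on_uniform_models():
    atoms = [AtomRecord(f"C{i}", "C", [i, 0, 0], b=25.0) for i in range(1, 7)]
    residues = [ResidueRecord("A", i, "ALA", [a]) for i, a in enumerate(atoms)]
    residues += [ResidueRecord("B", i, "ALA", [a.copy()]) for i, a in enumerate(atoms)]
    from glycurate.model import detect_flat_b
    m = StructureModel(residues=residues, cell=(20, 20, 20, 90, 90, 90))
    assert detect_flat_b(m) == pytest.approx(25.0)
    m.residues[0].atoms[0].b = 40.0
    assert detect_flat_b(m) is None
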