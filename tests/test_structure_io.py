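"""Structure I/O round-trips and charge assignment."""

import numpy as np
import pytest

import redoxmap as rm
from redoxmap.charges import formal_residue_charge
from redoxmap.structure import Atom, MolecularModel, ParseError
from redoxmap.synthetic import make_patch_receptor, make_ring_ligand

TOY_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
HETATM    3 FE   HEC A   9       0.000   0.000   0.000  1.00  0.00          FE
END
"""


def _residue(resname, names, resid=1, chain="A", offset=0.0):
    return [
        Atom(serial=i + 1, name=n, residue_name=resname, residue_id=resid,
             chain=chain, position=np.array([offset + i, 0.0, 0.0]))
        for i, n in enumerate(names)
    ]


class TestPDB:
    def test_toy_pdb_positions_and_cofactor(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        model = rm.read_pdb(p)
        assert len(model) == 3
        np.testing.assert_allclose(model.atoms[0].position, [1.0, 2.0, 3.0])
        assert model.atoms[0].charge == 0.0 and model.atoms[0].radius == 0.0
        assert model.atoms[2].cofactor_id == "heme9"
        assert model.hemes == ["heme9"]

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ParseError, match="empty"):
            rm.read_pdb(p)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  N   ALA A   1       1.000   2.000\n")
        with pytest.raises(ParseError, match="line 1"):
            rm.read_pdb(p)

    def test_synthetic_fixture_roundtrip_field_by_field(self, tmp_path):
        model = make_patch_receptor(seed=3)
        p = tmp_path / "rec.pdb"
        rm.write_pdb(model, p)
        back = rm.read_pdb(p)
        assert len(back) == len(model)
        for a, b in zip(model.atoms, back.atoms):
            assert (a.name, a.residue_name, a.residue_id, a.chain) == \
                   (b.name, b.residue_name, b.residue_id, b.chain)
            np.testing.assert_allclose(a.position, b.position, atol=1.5e-3)
            assert a.cofactor_id == b.cofactor_id
        assert back.hemes == model.hemes


class TestPQR:
    def test_roundtrip_preserves_fields(self, tmp_path):
        model = make_ring_ligand(seed=5)
        p = tmp_path / "lig.pqr"
        rm.write_pqr(model, p)
        back = rm.read_pqr(p)
        assert len(back) == len(model)
        for a, b in zip(model.atoms, back.atoms):
            assert a.serial == b.serial and a.name == b.name
            assert (a.residue_name, a.residue_id, a.chain) == \
                   (b.residue_name, b.residue_id, b.chain)
            np.testing.assert_allclose(a.position, b.position, atol=1.5e-3)
            assert abs(a.charge - b.charge) < 1.5e-4
            assert abs(a.radius - b.radius) < 1.5e-3
            assert a.cofactor_id == b.cofactor_id

    def test_charge_column_parsed(self, tmp_path):
        p = tmp_path / "one.pqr"
        p.write_text("ATOM 1 OD2 ASP A 1 0.000 0.000 0.000 -0.5500 1.400\n")
        model = rm.read_pqr(p)
        assert model.atoms[0].charge == pytest.approx(-0.55)
        assert model.atoms[0].radius == pytest.approx(1.40)

    def test_missing_radius_column_errors(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 OD2 ASP 1 0.0 0.0 0.0 -0.55\n")
        with pytest.raises(ParseError, match="charge/radius"):
            rm.read_pqr(p)


class TestDX:
    def test_tiny_roundtrip_identical(self, tmp_path):
        grid = rm.PotentialGrid(origin=np.array([-1.0, 0.0, 2.5]), spacing=0.5,
                                values=np.arange(8.0).reshape(2, 2, 2))
        p = tmp_path / "g.dx"
        rm.write_dx(grid, p)
        back = rm.read_dx(p)
        np.testing.assert_allclose(back.origin, grid.origin)
        assert back.spacing == pytest.approx(grid.spacing)
        np.testing.assert_allclose(back.values, grid.values)

    def test_field_grid_roundtrip_close(self, tmp_path):
        model = make_ring_ligand(seed=1)
        grid = rm.potential_grid(model, spacing=3.0, padding=6.0, ionic_strength_M=0.05)
        p = tmp_path / "field.dx"
        rm.write_dx(grid, p)
        back = rm.read_dx(p)
        np.testing.assert_allclose(back.values, grid.values, atol=1e-6)

    def test_griddata_reads_our_dx(self, tmp_path):
        # cross-check against the independent OpenDX implementation
        from gridData import Grid

        grid = rm.PotentialGrid(origin=np.zeros(3), spacing=1.5,
                                values=np.arange(27.0).reshape(3, 3, 3))
        p = tmp_path / "g.dx"
        rm.write_dx(grid, p)
        g = Grid(str(p))
        np.testing.assert_allclose(g.grid, grid.values)
        np.testing.assert_allclose(g.origin, grid.origin)

    def test_truncated_file_errors(self, tmp_path):
        grid = rm.PotentialGrid(origin=np.zeros(3), spacing=1.0,
                                values=np.zeros((3, 3, 3)))
        p = tmp_path / "g.dx"
        rm.write_dx(grid, p)
        text = p.read_text().splitlines()
        p.write_text("\n".join(text[:10]) + "\n")
        with pytest.raises(ParseError, match="truncated|incomplete"):
            rm.read_dx(p)

    def test_nonuniform_spacing_errors(self, tmp_path):
        grid = rm.PotentialGrid(origin=np.zeros(3), spacing=1.0,
                                values=np.zeros((2, 2, 2)))
        p = tmp_path / "g.dx"
        rm.write_dx(grid, p)
        p.write_text(p.read_text().replace(
            "delta 0.000000e+00 1.000000e+00 0.000000e+00",
            "delta 0.000000e+00 2.000000e+00 0.000000e+00"))
        with pytest.raises(ParseError, match="non-uniform"):
            rm.read_dx(p)


class TestAssignCharges:
    def test_single_asp_sidechain_is_minus_one(self):
        atoms = _residue("ASP", ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"])
        model = rm.assign_charges(MolecularModel(atoms=atoms))
        by_name = {a.name: a.charge for a in model.atoms}
        assert by_name["OD2"] == pytest.approx(-1.0)
        # single residue carries both termini: -1 (side) + 1 (N) - 1 (O)
        assert model.net_charge == pytest.approx(-1.0)

    def test_tripeptide_lys_gly_glu_is_neutral(self):
        atoms = (
            _residue("LYS", ["N", "CA", "C", "O", "CB", "NZ"], resid=1)
            + _residue("GLY", ["N", "CA", "C", "O"], resid=2, offset=10)
            + _residue("GLU", ["N", "CA", "C", "O", "OXT", "CD", "OE2"], resid=3, offset=20)
        )
        for i, a in enumerate(atoms):
            a.serial = i + 1
        model = rm.assign_charges(MolecularModel(atoms=atoms))
        # +1 Lys, +1 N-terminus, -1 Glu, -1 C-terminus
        assert model.net_charge == pytest.approx(0.0)

    def test_ferrous_heme_is_one_electron_lower(self):
        atoms = _residue("HIS", ["N", "CA", "C", "O"], resid=1)
        atoms += [Atom(serial=9, name="FE", residue_name="HEC", residue_id=3, chain="A",
                       position=np.array([5.0, 0, 0]), cofactor_id="heme3")]
        model = MolecularModel(atoms=atoms)
        ferric = rm.assign_charges(model)
        ferrous = rm.assign_charges(
            model, redox=rm.RedoxStateSpec({"heme3": "ferrous"}))
        assert ferric.net_charge - ferrous.net_charge == pytest.approx(1.0)

    def test_redox_spec_for_absent_heme_errors(self):
        atoms = _residue("GLY", ["N", "CA", "C", "O"])
        with pytest.raises(KeyError, match="absent"):
            rm.assign_charges(MolecularModel(atoms=atoms),
                              redox=rm.RedoxStateSpec({"heme7": "ferrous"}))

    def test_unknown_residue_warned_and_zeroed(self):
        atoms = _residue("XYZ", ["C1", "C2"])
        with pytest.warns(UserWarning, match="XYZ"):
            model = rm.assign_charges(MolecularModel(atoms=atoms))
        assert model.net_charge == 0.0

    def test_idempotent(self):
        atoms = (_residue("LYS", ["N", "CA", "C", "O", "NZ"], resid=1)
                 + _residue("ASP", ["N", "CA", "C", "O", "OD2"], resid=2, offset=10))
        for i, a in enumerate(atoms):
            a.serial = i + 1
        once = rm.assign_charges(MolecularModel(atoms=atoms))
        twice = rm.assign_charges(once)
        np.testing.assert_array_equal(once.charges(), twice.charges())

    @pytest.mark.parametrize("sequence", [
        ["ALA", "ASP", "LYS"],
        ["GLU", "GLU", "ARG", "SER"],
        ["MET", "HIS", "THR", "LYS", "ASP", "GLY"],
    ])
    def test_net_charge_matches_per_residue_lookup(self, sequence):
        """Distributed charges must sum to the tabulated formal charges."""
        atoms = []
        serial = 1
        names = {"ASP": ["N", "CA", "C", "O", "OD2"], "GLU": ["N", "CA", "C", "O", "OE2"],
                 "LYS": ["N", "CA", "C", "O", "NZ"], "ARG": ["N", "CA", "C", "O", "CZ"]}
        for i, res in enumerate(sequence):
            for n in names.get(res, ["N", "CA", "C", "O"]):
                atoms.append(Atom(serial=serial, name=n, residue_name=res,
                                  residue_id=i + 1, chain="A",
                                  position=np.array([serial * 2.0, 0, 0])))
                serial += 1
        model = rm.assign_charges(MolecularModel(atoms=atoms))
        expected = sum(
            formal_residue_charge(res, n_term=(i == 0), c_term=(i == len(sequence) - 1))
            for i, res in enumerate(sequence)
        )
        assert model.net_charge == pytest.approx(expected)

    def test_set_redox_state_touches_only_iron(self):
        lig = make_ring_ligand(seed=2)
        ferrous = rm.set_redox_state(lig, rm.RedoxStateSpec({"heme1": "ferrous"}))
        assert lig.net_charge - ferrous.net_charge == pytest.approx(1.0)
        changed = np.nonzero(lig.charges() != ferrous.charges())[0]
        assert len(changed) == 1
        assert lig.atoms[changed[0]].name == "FE"

    def test_unsupported_ph_errors(self):
        atoms = _residue("GLY", ["N", "CA", "C", "O"])
        with pytest.raises(ValueError, match="pH"):
            rm.assign_charges(MolecularModel(atoms=atoms), pH=5.0)
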