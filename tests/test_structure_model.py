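import numpy as np
import pytest

from ligdyn.errors import AnnotationError, ParseError, SelectionError, StructureError
from ligdyn.structure_model import (
    AtomSelection,
    annotate_chemistry,
    read_frame_series,
    select_atoms,
    write_frame_series,
)
from ligdyn.synthetic_data import FluctuationSpec, LigandSpec, make_fluctuation_trajectory, make_toy_complex


def _pdb_line(record, serial, name, resname, chain, resseq, x, y, z, element):
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_field} {resname:>3s} {chain}{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n")


def _two_model_pdb(tmp_path, n_atoms=10, name="two.pdb"):
    lines = []
    for model in (1, 2):
        lines.append(f"MODEL {model:>8d}\n")
        for i in range(n_atoms):
            lines.append(_pdb_line("ATOM", i + 1, "CA", "GLY", "A", i + 1,
                                   float(i), float(model), 0.0, "C"))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    p = tmp_path / name
    p.write_text("".join(lines))
    return p


class TestReadFrameSeries:
    def test_two_models_ten_atoms(self, tmp_path):
        series = read_frame_series(_two_model_pdb(tmp_path))
        assert series.n_frames == 2
        assert series.n_atoms == 10

    def test_hetatm_ligand_code_sets_mask(self, tmp_path):
        p = tmp_path / "lig.pdb"
        p.write_text(
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + _pdb_line("HETATM", 2, "C1", "INH", "A", 386, 3, 0, 0, "C")
            + "END\n"
        )
        series = read_frame_series(p, ligand_codes=("INH",))
        assert series.ligand_mask.tolist() == [False, True]
        assert series.atoms[1].is_ligand

    def test_waters_dropped_by_default(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + _pdb_line("HETATM", 2, "O", "HOH", "A", 500, 5, 5, 5, "O")
        )
        series = read_frame_series(p)
        assert series.n_atoms == 1

    def test_round_trip_preserves_coords_to_3_decimals(self, tmp_path):
        base = make_toy_complex(8, LigandSpec(), seed=3)
        traj = make_fluctuation_trajectory(
            base, FluctuationSpec(sigma_nm=np.full(8, 0.05), n_frames=3, seed=4)
        )
        path = tmp_path / "rt.pdb"
        write_frame_series(traj, path)
        back = read_frame_series(path)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        assert [a.name for a in back.atoms] == [a.name for a in traj.atoms]
        np.testing.assert_allclose(back.frames, np.round(traj.frames, 3), atol=5e-4)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        good = _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
        bad = good[:30] + "  notnum" + good[38:]
        p.write_text(good + bad)
        with pytest.raises(ParseError, match="line 2"):
            read_frame_series(p)

    def test_inconsistent_model_atom_count(self, tmp_path):
        p = tmp_path / "inc.pdb"
        p.write_text(
            "MODEL        1\n"
            + _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + _pdb_line("ATOM", 2, "CA", "GLY", "A", 2, 1, 0, 0, "C")
            + "ENDMDL\nMODEL        2\n"
            + _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + "ENDMDL\n"
        )
        with pytest.raises(StructureError, match="model 2"):
            read_frame_series(p)

    def test_insertion_code_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        line = _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
        line = line[:26] + "A" + line[27:]
        p.write_text(line)
        with pytest.raises(ParseError, match="insertion"):
            read_frame_series(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError):
            read_frame_series(tmp_path / "nope.pdb")


class TestAnnotateChemistry:
    def _mini(self, tmp_path, resname, atoms):
        lines = []
        for i, (name, element, xyz) in enumerate(atoms):
            lines.append(_pdb_line("ATOM", i + 1, name, resname, "A", 1, *xyz, element))
        p = tmp_path / f"{resname}.pdb"
        p.write_text("".join(lines))
        return read_frame_series(p)

    def test_asp_gets_one_anion_group(self, tmp_path):
        series = self._mini(tmp_path, "ASP", [
            ("N", "N", (0, 0, 0)), ("H", "H", (0, -1, 0)), ("CA", "C", (1.5, 0, 0)),
            ("C", "C", (2.5, 1, 0)), ("O", "O", (2.5, 1, 1.2)), ("CB", "C", (1.5, 1.5, 0)),
            ("CG", "C", (1.5, 3.0, 0)), ("OD1", "O", (0.5, 3.8, 0)), ("OD2", "O", (2.5, 3.8, 0)),
        ])
        annotate_chemistry(series)
        anions = [g for s, g in series.charged_groups if s < 0]
        assert len(anions) == 1
        names = {series.atoms[i].name for i in anions[0]}
        assert names == {"OD1", "OD2"}

    def test_arg_gets_one_cation_group(self, tmp_path):
        series = self._mini(tmp_path, "ARG", [
            ("N", "N", (0, 0, 0)), ("H", "H", (0, -1, 0)), ("CA", "C", (1.5, 0, 0)),
            ("C", "C", (2.5, 1, 0)), ("O", "O", (2.5, 1, 1.2)),
            ("NE", "N", (4, 0, 0)), ("HE", "H", (4, -1, 0)),
            ("CZ", "C", (5.3, 0, 0)),
            ("NH1", "N", (6.0, 1.1, 0)), ("HH11", "H", (7.0, 1.1, 0)),
            ("NH2", "N", (6.0, -1.1, 0)), ("HH21", "H", (7.0, -1.1, 0)),
        ])
        annotate_chemistry(series)
        cations = [g for s, g in series.charged_groups if s > 0]
        assert len(cations) == 1
        assert {series.atoms[i].name for i in cations[0]} == {"NE", "NH1", "NH2", "CZ"}

    def test_trp_registers_two_rings(self, tmp_path):
        # planar indole coordinates are unnecessary; membership is what matters
        ring5 = [("CG", (0, 0, 0)), ("CD1", (1.2, 0.8, 0)), ("NE1", (2.4, 0, 0)),
                 ("CE2", (2.0, -1.3, 0)), ("CD2", (0.6, -1.3, 0))]
        ring6_extra = [("CZ2", (2.8, -2.4, 0)), ("CH2", (2.2, -3.7, 0)),
                       ("CZ3", (0.8, -3.8, 0)), ("CE3", (0.0, -2.6, 0))]
        atoms = [("N", "N", (-2, 0, 0)), ("H", "H", (-2, -1, 0)), ("CA", "C", (-1, 0, 0)),
                 ("HE1", "H", (3.4, 0.4, 0))]
        atoms += [(n, "N" if n.startswith("N") else "C", xyz) for n, xyz in ring5 + ring6_extra]
        series = self._mini(tmp_path, "TRP", atoms)
        annotate_chemistry(series)
        assert len(series.rings) == 2
        assert sorted(len(r) for r in series.rings) == [5, 6]

    def test_unknown_residue_listed(self, tmp_path):
        series = self._mini(tmp_path, "XYZ", [("C1", "C", (0, 0, 0))])
        with pytest.raises(AnnotationError, match="XYZ"):
            annotate_chemistry(series)

    def test_missing_donor_hydrogen_raises(self, tmp_path):
        series = self._mini(tmp_path, "GLY", [
            ("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
            ("C", "C", (2.5, 1, 0)), ("O", "O", (2.5, 1, 1.2)),
        ])
        with pytest.raises(AnnotationError, match="GLY1.N"):
            annotate_chemistry(series)
        annotate_chemistry(series, require_hydrogens=False)  # lenient mode succeeds
        assert series.donor_pairs == []

    def test_polar_hydrogen_paired_with_single_donor(self, toy_complex):
        h_atoms = [i for i, a in enumerate(toy_complex.atoms) if "polar-hydrogen" in a.roles]
        for h in h_atoms:
            partners = [d for d, hh in toy_complex.donor_pairs if hh == h]
            assert len(partners) == 1


class TestSelectAtoms:
    def test_calpha_on_385_residue_protein(self):
        series = make_toy_complex(385, ligand_spec=None, seed=0)
        assert select_atoms(series, "calpha").size == 385

    def test_ligand_on_system_without_ligand(self):
        series = make_toy_complex(10, ligand_spec=None, seed=0)
        with pytest.raises(SelectionError):
            select_atoms(series, "ligand")

    def test_backbone_of_single_residue(self, toy_complex):
        idx = select_atoms(toy_complex, AtomSelection(
            atom_names=("N", "CA", "C", "O"), residue_range=(1, 1), ligand=False))
        assert idx.size == 4

    def test_unknown_named_selection(self, toy_complex):
        with pytest.raises(SelectionError):
            select_atoms(toy_complex, "sidechain")

    def test_selection_composition(self, toy_complex):
        calpha = set(select_atoms(toy_complex, "calpha"))
        backbone = set(select_atoms(toy_complex, "backbone"))
        protein = set(select_atoms(toy_complex, "protein"))
        ligand = set(select_atoms(toy_complex, "ligand"))
        assert calpha <= backbone <= protein
        assert protein.isdisjoint(ligand)
        assert protein | ligand == set(range(toy_complex.n_atoms))
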