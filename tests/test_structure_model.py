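import math

import numpy as np
import pytest

from critres.fixtures import ToySpec, make_toy
from critres.structure_model import (
    InteractionKind,
    StructureError,
    compute_sasa,
    detect_covalent_bonds,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
    hydrophobicity_class,
    read_structure,
    write_structure,
)
from conftest import make_structure

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       5.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       6.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       7.000   1.400   0.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N
ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60  0.00           N
ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_identity_parse(self):
        s = read_structure(MINI_PDB)
        assert len(s.residues) == 1
        assert s.n_atoms == 3
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]
        assert not any(a.is_sidechain for a in s.atoms)

    def test_toy_fixture_round(self):
        toy = make_toy(ToySpec(5, "extended"))
        s = read_structure(toy.pdb_text)
        assert len(s.residues) == 5
        assert s.n_atoms == 25  # N, CA, C, O, CB per residue

    @pytest.mark.parametrize("model_index,n_atoms", [(0, 2), (1, 3)])
    def test_nmr_model_selection(self, model_index, n_atoms):
        s = read_structure(TWO_MODEL_PDB, model_index=model_index)
        assert s.n_atoms == n_atoms

    def test_altloc_keeps_highest_occupancy(self):
        s = read_structure(ALTLOC_PDB)
        n_atom = s.residues[0].atom("N")
        assert n_atom.coords[0] == pytest.approx(9.0)

    def test_no_atoms_is_parse_error(self):
        with pytest.raises(StructureError):
            read_structure("HEADER  empty\nEND\n")

    def test_unknown_residue_warns_but_keeps_atoms(self):
        pdb = MINI_PDB.replace("ALA", "XXZ")
        with pytest.warns(UserWarning, match="unknown residue"):
            s = read_structure(pdb)
        assert s.n_atoms == 3
        assert s.residues[0].hydrophobicity_class == "none"

    def test_write_read_roundtrip(self):
        toy = make_toy(ToySpec(6, "helix_like", n_hbonds=3))
        s = read_structure(toy.pdb_text)
        s2 = read_structure(write_structure(s))
        assert s2.n_atoms == s.n_atoms
        assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
        np.testing.assert_allclose(s2.coords_array(), s.coords_array(),
                                   atol=1e-3)


class TestCovalentBonds:
    def test_pair_inside_cutoff(self):
        s = make_structure([("C1", "C", 1, (0, 0, 0)), ("C2", "C", 1, (1.5, 0, 0))])
        bonds = detect_covalent_bonds(s)
        assert len(bonds) == 1
        assert bonds[0].kind is InteractionKind.COVALENT_ROTATABLE
        assert bonds[0].bars == 5

    def test_pair_outside_cutoff(self):
        s = make_structure([("C1", "C", 1, (0, 0, 0)), ("C2", "C", 1, (5.0, 0, 0))])
        assert detect_covalent_bonds(s) == []

    def test_peptide_bond_is_locked(self):
        s = make_structure([("C", "C", 1, (0, 0, 0)), ("N", "N", 2, (1.33, 0, 0))])
        bonds = detect_covalent_bonds(s)
        assert len(bonds) == 1
        assert bonds[0].kind is InteractionKind.COVALENT_LOCKED
        assert bonds[0].bars == 6

    def test_carbonyl_is_locked_ring_rule(self):
        s = make_structure([("C", "C", 1, (0, 0, 0)), ("O", "O", 1, (1.23, 0, 0))])
        (bond,) = detect_covalent_bonds(s)
        assert bond.kind is InteractionKind.COVALENT_LOCKED

    def test_unknown_element_raises_naming_it(self):
        s = make_structure([("X1", "XQ", 1, (0, 0, 0)), ("C2", "C", 1, (1.5, 0, 0))])
        with pytest.raises(StructureError, match="XQ"):
            detect_covalent_bonds(s)

    def test_detection_is_order_independent(self):
        toy = make_toy(ToySpec(6, "helix_like", n_hbonds=4))
        s = read_structure(toy.pdb_text)
        lines = [l for l in toy.pdb_text.splitlines() if l.startswith("ATOM")]
        reversed_pdb = "\n".join(reversed(lines)) + "\nEND\n"
        s_rev = read_structure(reversed_pdb)
        keys = {b.key()[1:] for b in detect_covalent_bonds(s)}
        keys_rev = {b.key()[1:] for b in detect_covalent_bonds(s_rev)}
        # serials identical in both files, so the bond sets must agree
        assert keys == keys_rev

    def test_no_duplicate_bonds(self, toy_interactions):
        _, _, interactions = toy_interactions
        keys = [iv.key() for iv in interactions]
        assert len(keys) == len(set(keys))


class TestHydrogenBonds:
    def test_distance_only_branch(self):
        s = make_structure([("O", "O", 1, (0, 0, 0)), ("N", "N", 3, (2.9, 0, 0))])
        hb = detect_hydrogen_bonds(s, covalent=[])
        assert len(hb) == 1
        assert hb[0].bars == 5

    def test_too_far(self):
        s = make_structure([("O", "O", 1, (0, 0, 0)), ("N", "N", 3, (4.2, 0, 0))])
        assert detect_hydrogen_bonds(s, covalent=[]) == []

    def test_bad_angle_rejected_with_explicit_hydrogen(self):
        # D-H...A angle of 90 degrees: H equidistant corner
        s = make_structure([("N", "N", 1, (0, 0, 0)),
                            ("H", "H", 1, (0, 1.0, 0)),
                            ("O", "O", 3, (2.0, 1.0, 0))])
        cov = detect_covalent_bonds(s)
        assert detect_hydrogen_bonds(s, covalent=cov) == []

    def test_good_angle_accepted(self):
        s = make_structure([("N", "N", 1, (0, 0, 0)),
                            ("H", "H", 1, (1.0, 0, 0)),
                            ("O", "O", 3, (2.9, 0, 0))])
        cov = detect_covalent_bonds(s)
        hb = detect_hydrogen_bonds(s, covalent=cov)
        assert len(hb) == 1

    def test_intra_residue_excluded(self):
        s = make_structure([("O", "O", 1, (0, 0, 0)), ("N", "N", 1, (2.9, 0, 0))])
        assert detect_hydrogen_bonds(s, covalent=[]) == []


class TestHydrophobicTethers:
    def test_pair_inside_cutoff(self):
        s = make_structure([("CB", "C", 1, (0, 0, 0)), ("CB", "C", 3, (3.5, 0, 0))])
        th = detect_hydrophobic_tethers(s)
        assert len(th) == 1
        assert th[0].bars == 2

    def test_pair_outside_cutoff(self):
        s = make_structure([("CB", "C", 1, (0, 0, 0)), ("CB", "C", 3, (4.0, 0, 0))])
        assert detect_hydrophobic_tethers(s) == []

    def test_backbone_carbons_excluded(self):
        s = make_structure([("CA", "C", 1, (0, 0, 0)), ("CA", "C", 3, (3.5, 0, 0))])
        assert detect_hydrophobic_tethers(s) == []

    def test_sequence_neighbours_excluded(self):
        s = make_structure([("CB", "C", 1, (0, 0, 0)), ("CB", "C", 2, (3.5, 0, 0))])
        assert detect_hydrophobic_tethers(s) == []


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = make_structure([("CB", "C", 1, (0, 0, 0))])
        sasa = compute_sasa(s)
        expect = 4 * math.pi * (1.7 + 1.4) ** 2
        assert sasa[("A", 1, "")] == pytest.approx(expect, rel=0.02)

    def test_enclosed_atom_is_zero(self):
        shell = []
        for i, z in enumerate(np.linspace(-1, 1, 26)):
            phi = i * 2.4
            r = math.sqrt(max(0.0, 1 - z * z))
            shell.append(("CB", "C", 2,
                          (2.2 * r * math.cos(phi), 2.2 * r * math.sin(phi),
                           2.2 * z)))
        s = make_structure([("CB", "C", 1, (0, 0, 0))] + shell)
        sasa = compute_sasa(s)
        assert sasa[("A", 1, "")] == 0.0

    def test_rigid_motion_invariance(self):
        from dataclasses import replace

        from scipy.spatial.transform import Rotation

        from critres.structure_model import Residue, Structure

        toy = make_toy(ToySpec(4, "extended", seed=0))
        s1 = read_structure(toy.pdb_text)
        R = Rotation.from_euler("zyx", [31.0, -57.0, 112.0], degrees=True)
        shift = np.array([3.1, -8.2, 0.7])
        moved = [
            Residue(r.residue_key, r.aa_type,
                    [replace(a, coords=R.apply(a.coords) + shift)
                     for a in r.atoms])
            for r in s1.residues
        ]
        s2 = Structure("moved", moved, {"A": moved})
        sasa1 = compute_sasa(s1)
        sasa2 = compute_sasa(s2)
        for key in sasa1:
            assert sasa1[key] == pytest.approx(sasa2[key], abs=1e-6)


def test_hydrophobicity_classes():
    assert hydrophobicity_class("VAL") == "very"
    assert hydrophobicity_class("ALA") == "slight"
    assert hydrophobicity_class("ASP") == "none"
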