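import warnings

import numpy as np
import pytest

from critres.fixtures import ToySpec, make_toy
from critres.mechanical_model import BodyBarGraph
from critres.structure_model import (
    Atom,
    Residue,
    Structure,
    detect_covalent_bonds,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="unknown residue name")
        warnings.filterwarnings("ignore", message=".*already glycine.*")
        warnings.filterwarnings("ignore", message=".*already alanine.*")
        yield


def make_structure(atom_specs, aa_type="ALA", name="synthetic"):
    """Build a Structure from (name, element, resnum, xyz[, sidechain]) tuples.

    A hand-assembled stand-in for parsed PDB data, used to exercise the
    interaction detectors on exact geometries.
    """
    residues = {}
    for i, spec in enumerate(atom_specs, 1):
        aname, element, resnum, xyz = spec[:4]
        backbone = {"N", "CA", "C", "O", "OXT", "H", "HA"}
        sidechain = spec[4] if len(spec) > 4 else aname not in backbone
        key = ("A", resnum, "")
        atom = Atom(serial=i, name=aname, element=element, residue_key=key,
                    coords=np.asarray(xyz, dtype=float),
                    is_sidechain=sidechain, is_cbeta=aname == "CB")
        residues.setdefault(key, []).append(atom)
    res_list = [Residue(key, aa_type, atoms) for key, atoms in residues.items()]
    return Structure(name=name, residues=res_list,
                     chains={"A": res_list})


@pytest.fixture
def synthetic_structure_factory():
    return make_structure


def graph_of(n, edges):
    return BodyBarGraph(n_bodies=n,
                        edges=[(u, v, m, "test") for u, v, m in edges])


@pytest.fixture
def hinge_toy():
    """Two rigid domains bridged by two tethers through one anchor region."""
    return make_toy(ToySpec(8, "two_domain_hinge", n_hbonds=0, n_tethers=2))


@pytest.fixture
def toy_interactions():
    """(structure, interactions) of the hinge toy, fully detected."""
    from critres.structure_model import read_structure

    toy = make_toy(ToySpec(8, "two_domain_hinge", n_hbonds=0, n_tethers=2))
    s = read_structure(toy.pdb_text, name="toy")
    cov = detect_covalent_bonds(s)
    hb = detect_hydrogen_bonds(s, covalent=cov)
    th = detect_hydrophobic_tethers(s)
    return toy, s, cov + hb + th
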