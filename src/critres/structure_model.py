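"""Protein structures and the chemical interactions that parameterize rigidity.

Parses PDB text into a light-weight :class:`Structure` (atoms grouped into
residues and chains), detects the stabilizing interactions used by the
body-bar mechanical model -- covalent bonds (rotatable or locked), hydrogen
bonds, hydrophobic tethers -- and computes per-residue solvent-accessible
surface area with an internal Shrake-Rupley implementation.

Detection cutoffs follow the FIRST/KINARI lineage of rigidity software:
covalent pairs within the covalent-radius sum + 0.4 A; hydrogen bonds by a
donor-acceptor distance of 3.5 A (plus a D-H...A angle of at least 110 deg
when explicit hydrogens are present); hydrophobic tethers between side-chain
C/S atoms within the van der Waals sum + 0.25 A. All cutoffs are arguments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Interaction",
    "InteractionKind",
    "HBondParams",
    "StructureError",
    "read_structure",
    "write_structure",
    "detect_covalent_bonds",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_tethers",
    "compute_sasa",
    "interactions_to_tsv",
    "hydrophobicity_class",
]


class StructureError(ValueError):
    """Raised for unparsable structures or unmodelable chemistry."""


# Single-bond covalent radii (A), Cordero-style values as used by FIRST/KINARI.
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02,
    "P": 1.06, "SE": 1.16, "F": 0.64, "CL": 0.99, "BR": 1.14, "I": 1.33,
}

# van der Waals radii (A) for tether detection and SASA.
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

BACKBONE_NAMES = {
    "N", "CA", "C", "O", "OXT",
    # backbone hydrogens (amide H, N-terminal H1-3, alpha H / glycine HA2-3)
    "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT",
    "1H", "2H", "3H",
}

# Table-style hydrophobicity classes of the 20 standard amino acids.
VERY_HYDROPHOBIC = {"VAL", "LEU", "ILE", "PHE", "MET", "TRP", "CYS", "THR"}
SLIGHTLY_HYDROPHOBIC = {"ALA", "TYR", "HIS", "LYS"}
STANDARD_AA = VERY_HYDROPHOBIC | SLIGHTLY_HYDROPHOBIC | {
    "GLY", "SER", "PRO", "ASN", "GLN", "ASP", "GLU", "ARG",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


def hydrophobicity_class(aa_type: str) -> str:
    """Classify a 3-letter residue code as 'very', 'slight' or 'none'."""
    aa = aa_type.upper()
    if aa in VERY_HYDROPHOBIC:
        return "very"
    if aa in SLIGHTLY_HYDROPHOBIC:
        return "slight"
    return "none"


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_key: tuple  # (chain id, residue number, insertion code)
    coords: np.ndarray  # shape (3,), Angstrom
    is_sidechain: bool
    is_cbeta: bool

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise StructureError(f"atom {self.serial}: empty element")

    def __hash__(self):
        return hash((self.serial, self.name, self.residue_key))

    def __eq__(self, other):
        if not isinstance(other, Atom):
            return NotImplemented
        return (self.serial, self.name, self.residue_key) == (
            other.serial, other.name, other.residue_key)


@dataclass
class Residue:
    residue_key: tuple
    aa_type: str
    atoms: list = field(default_factory=list)
    sasa: Optional[float] = None
    hydrophobicity_class: str = "none"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def sidechain_atoms(self) -> list:
        return [a for a in self.atoms if a.is_sidechain]


@dataclass
class Structure:
    name: str
    residues: list  # ordered list of Residue
    chains: dict = field(default_factory=dict)  # chain id -> list of Residue

    @property
    def atoms(self) -> list:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, key: tuple) -> Residue:
        for r in self.residues:
            if r.residue_key == key:
                return r
        raise KeyError(key)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


class InteractionKind(str, Enum):
    COVALENT_ROTATABLE = "covalent_rotatable"
    COVALENT_LOCKED = "covalent_locked"
    HBOND = "hbond"
    HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True)
class Interaction:
    """A typed stabilizing constraint between two atoms, with bar multiplicity."""
    kind: InteractionKind
    atom_a: Atom
    atom_b: Atom
    bars: int
    provenance: str = ""

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise StructureError("interaction endpoints must differ")
        if not (1 <= self.bars <= 6):
            raise StructureError("bar multiplicity must be in 1..6")
        if self.kind is InteractionKind.COVALENT_ROTATABLE and self.bars != 5:
            raise StructureError("rotatable covalent bonds are hinges (5 bars)")
        if self.kind is InteractionKind.COVALENT_LOCKED and self.bars != 6:
            raise StructureError("locked covalent bonds carry 6 bars")

    @property
    def is_covalent(self) -> bool:
        return self.kind in (InteractionKind.COVALENT_ROTATABLE,
                             InteractionKind.COVALENT_LOCKED)

    def key(self) -> tuple:
        a, b = sorted((self.atom_a.serial, self.atom_b.serial))
        return (self.kind.value, a, b)

    def distance(self) -> float:
        return float(np.linalg.norm(self.atom_a.coords - self.atom_b.coords))


@dataclass
class HBondParams:
    max_da_distance: float = 3.5   # donor-acceptor, Angstrom
    min_dha_angle: float = 110.0   # degrees, applied only with explicit H
    bars: int = 5


# ---------------------------------------------------------------------------
# Parsing

def read_structure(pdb_text: str, model_index: int = 0,
                   chain_filter: Optional[set] = None,
                   keep_hetatm: bool = False,
                   name: str = "structure") -> Structure:
    """Parse PDB text into a Structure.

    Only the selected model of a multi-model (NMR) file is read. Alternate
    locations keep the highest-occupancy conformer (ties broken toward
    altloc 'A'); HETATM groups and waters are dropped unless requested.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no ATOM records found")
    if model_index >= len(st):
        raise StructureError(
            f"model_index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    residues: list = []
    chains: dict = {}
    n_atom_records = 0
    for chain in model:
        cid = chain.name
        if chain_filter is not None and cid not in chain_filter:
            continue
        for res in chain:
            if res.het_flag == "H" and not keep_hetatm:
                continue
            if res.name in WATER_NAMES:
                continue
            aa = res.name
            if aa not in STANDARD_AA and res.het_flag != "H":
                warnings.warn(
                    f"unknown residue name {aa!r} at {cid}{res.seqid.num}; "
                    "atoms kept with hydrophobicity class 'none'")
            key = (cid, res.seqid.num, res.seqid.icode.strip() or "")
            # altloc resolution: group by atom name, keep best occupancy
            by_name: dict = {}
            for at in res:
                n_atom_records += 1
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                    continue
                if at.occ > prev.occ or (
                        at.occ == prev.occ and (at.altloc or "Z") < (prev.altloc or "Z")):
                    by_name[at.name] = at
            atoms = []
            for at in by_name.values():
                elem = at.element.name.upper() or at.name[:1].upper()
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=elem,
                    residue_key=key,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_sidechain=at.name not in BACKBONE_NAMES,
                    is_cbeta=at.name == "CB",
                ))
            if not atoms:
                continue
            atoms.sort(key=lambda a: a.serial)
            residue = Residue(key, aa, atoms,
                              hydrophobicity_class=hydrophobicity_class(aa))
            residues.append(residue)
            chains.setdefault(cid, []).append(residue)

    if not residues:
        raise StructureError("no ATOM records found")
    return Structure(name=name, residues=residues, chains=chains)


def write_structure(structure: Structure) -> str:
    """Emit the structure back as minimal PDB text (ATOM records + END)."""
    lines = []
    for res in structure.residues:
        cid, num, icode = res.residue_key
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4s}{res.aa_type:>4s} {cid:1s}"
                f"{num:4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Covalent bonds

# Locked (non-rotatable) bonds from residue templates: peptide bond, sp2
# carbonyl/carboxylate/amide/guanidinium groups, and aromatic or proline rings.
_LOCKED_PAIRS = {
    "*": {("C", "O"), ("C", "OXT")},
    "ARG": {("CZ", "NH1"), ("CZ", "NH2"), ("CZ", "NE")},
    "ASN": {("CG", "OD1"), ("CG", "ND2")},
    "GLN": {("CD", "OE1"), ("CD", "NE2")},
    "ASP": {("CG", "OD1"), ("CG", "OD2")},
    "GLU": {("CD", "OE1"), ("CD", "OE2")},
    "HIS": {("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
            ("NE2", "CD2"), ("CD2", "CG")},
    "PHE": {("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")},
    "TYR": {("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")},
    "TRP": {("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"),
            ("CE2", "CD2"), ("CD2", "CG"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")},
    "PRO": {("N", "CD"), ("CD", "CG"), ("CG", "CB"), ("CB", "CA")},
}


def _is_locked(a: Atom, b: Atom, res_a: str, res_b: str) -> bool:
    if a.residue_key != b.residue_key:
        # peptide bond C(i)-N(i+1)
        return {a.name, b.name} == {"C", "N"}
    pair = (a.name, b.name)
    rpair = (b.name, a.name)
    tmpl = _LOCKED_PAIRS.get(res_a, set()) | _LOCKED_PAIRS["*"]
    return pair in tmpl or rpair in tmpl


def detect_covalent_bonds(structure: Structure, tolerance: float = 0.4,
                          include_interchain: bool = False) -> list:
    """Distance-based covalent bond detection.

    Atom pairs closer than the sum of covalent radii + ``tolerance`` become
    bonds; peptide bonds, ring bonds and template double bonds are locked
    (6 bars), everything else is a rotatable hinge (5 bars).
    """
    atoms = structure.atoms
    res_of = {}
    for r in structure.residues:
        for a in r.atoms:
            res_of[a.serial] = r
    radii = []
    for a in atoms:
        r = COVALENT_RADII.get(a.element.upper())
        if r is None:
            raise StructureError(
                f"no covalent radius for element {a.element!r} (atom {a.serial})")
        radii.append(r)
    coords = np.array([a.coords for a in atoms])
    rmax = max(radii) if radii else 0.0
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2 * rmax + tolerance)
    out = []
    for i, j in sorted(pairs):
        a, b = atoms[i], atoms[j]
        cutoff = radii[i] + radii[j] + tolerance
        d = np.linalg.norm(a.coords - b.coords)
        if d > cutoff:
            continue
        if a.residue_key[0] != b.residue_key[0] and not include_interchain:
            continue
        ra, rb = res_of[a.serial], res_of[b.serial]
        if _is_locked(a, b, ra.aa_type, rb.aa_type):
            kind, bars, prov = InteractionKind.COVALENT_LOCKED, 6, "template-locked"
        else:
            kind, bars, prov = InteractionKind.COVALENT_ROTATABLE, 5, "distance"
        out.append(Interaction(kind, a, b, bars, prov))
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds

_DONOR_HEAVY = {"N"}               # any nitrogen
_DONOR_HYDROXYL = {"OG", "OG1", "OH"}   # Ser/Thr/Tyr hydroxyls
_ACCEPTOR_N = {"ND1", "NE2"}       # His imidazole nitrogens


def _hbond_donors(structure: Structure) -> list:
    donors = []
    for r in structure.residues:
        for a in r.atoms:
            if a.element == "N" and not (r.aa_type == "PRO" and a.name == "N"):
                donors.append(a)
            elif a.name in _DONOR_HYDROXYL:
                donors.append(a)
    return donors


def _hbond_acceptors(structure: Structure) -> list:
    acc = []
    for r in structure.residues:
        for a in r.atoms:
            if a.element == "O":
                acc.append(a)
            elif r.aa_type == "HIS" and a.name in _ACCEPTOR_N:
                acc.append(a)
    return acc


def detect_hydrogen_bonds(structure: Structure,
                          params: Optional[HBondParams] = None,
                          covalent: Optional[list] = None) -> list:
    """Geometric hydrogen-bond detection.

    Donor-acceptor distance <= ``params.max_da_distance``; when the donor has
    explicit hydrogens the best D-H...A angle must reach
    ``params.min_dha_angle``. Intra-residue pairs, covalently bonded pairs and
    1-3 pairs (atoms sharing a covalent neighbour) are excluded.
    """
    params = params or HBondParams()
    if covalent is None:
        covalent = detect_covalent_bonds(structure)
    bonded: dict = {}
    for iv in covalent:
        bonded.setdefault(iv.atom_a.serial, set()).add(iv.atom_b.serial)
        bonded.setdefault(iv.atom_b.serial, set()).add(iv.atom_a.serial)

    donors = _hbond_donors(structure)
    acceptors = _hbond_acceptors(structure)
    if not donors or not acceptors:
        return []
    atoms_by_serial = {a.serial: a for a in structure.atoms}
    hydrogens: dict = {}
    for a in structure.atoms:
        if a.element in ("H", "D"):
            for heavy in bonded.get(a.serial, ()):
                hydrogens.setdefault(heavy, []).append(a)

    acc_tree = cKDTree(np.array([a.coords for a in acceptors]))
    out = []
    seen = set()
    for d_atom in donors:
        idxs = acc_tree.query_ball_point(d_atom.coords, params.max_da_distance)
        for k in sorted(idxs):
            a_atom = acceptors[k]
            if a_atom.serial == d_atom.serial:
                continue
            if a_atom.residue_key == d_atom.residue_key:
                continue
            nb_d = bonded.get(d_atom.serial, set())
            if a_atom.serial in nb_d:
                continue
            if nb_d & bonded.get(a_atom.serial, set()):
                continue  # 1-3 pair through a shared covalent neighbour
            hs = hydrogens.get(d_atom.serial, [])
            if hs:
                best = max(_dha_angle(d_atom, h, a_atom) for h in hs)
                if best < params.min_dha_angle:
                    continue
                prov = f"D-A<= {params.max_da_distance}, DHA {best:.0f}deg"
            else:
                prov = f"D-A<= {params.max_da_distance} (no explicit H)"
            key = tuple(sorted((d_atom.serial, a_atom.serial)))
            if key in seen:
                continue
            seen.add(key)
            out.append(Interaction(InteractionKind.HBOND, d_atom, a_atom,
                                   params.bars, prov))
    return out


def _dha_angle(d: Atom, h: Atom, a: Atom) -> float:
    v1 = d.coords - h.coords
    v2 = a.coords - h.coords
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Hydrophobic tethers

def detect_hydrophobic_tethers(structure: Structure, slack: float = 0.25,
                               bars: int = 2) -> list:
    """C/S side-chain atom pairs from sequence-distant residues within the
    van der Waals radius sum + ``slack``."""
    cands = []
    for r in structure.residues:
        for a in r.atoms:
            if a.is_sidechain and a.element in ("C", "S"):
                cands.append(a)
    if len(cands) < 2:
        return []
    coords = np.array([a.coords for a in cands])
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) for a in cands])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(float(2 * radii.max() + slack))
    out = []
    for i, j in sorted(pairs):
        a, b = cands[i], cands[j]
        if a.residue_key == b.residue_key:
            continue
        same_chain = a.residue_key[0] == b.residue_key[0]
        if same_chain and abs(a.residue_key[1] - b.residue_key[1]) < 2:
            continue
        cutoff = radii[i] + radii[j] + slack
        if np.linalg.norm(a.coords - b.coords) <= cutoff:
            out.append(Interaction(InteractionKind.HYDROPHOBIC, a, b, bars,
                                   f"vdW+{slack}"))
    return out


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into their principal-axes frame (sign-fixed).

    Makes the discretized surface areas exactly invariant under rigid
    transforms of the input, since the sphere point set is then expressed in
    a molecule-fixed frame.
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return centered
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1]  # descending variance
    for k in range(3):
        j = int(np.argmax(np.abs(centered @ axes[:, k])))
        if (centered @ axes[:, k])[j] < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return centered @ axes


def compute_sasa(structure: Structure, probe: float = 1.4,
                 n_points: int = 960, include_hydrogens: bool = True) -> dict:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Rolls a ``probe``-radius sphere over the atoms using a deterministic
    golden-spiral point set expressed in the molecule's principal-axes frame,
    so results are invariant under rigid transforms of the structure; a
    residue's SASA is the sum over its atoms.
    """
    atoms = [a for a in structure.atoms
             if include_hydrogens or a.element not in ("H", "D")]
    if not atoms:
        return {}
    coords = _canonical_frame(np.array([a.coords for a in atoms]))
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) + probe
                      for a in atoms])
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(atoms))
    rmax = radii.max()
    for i in range(len(atoms)):
        test = coords[i] + radii[i] * pts
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                if j != i]
        if nbrs:
            d = np.linalg.norm(test[:, None, :] - coords[nbrs][None, :, :], axis=2)
            buried = (d < radii[nbrs][None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * n_acc / n_points

    sasa: dict = {}
    serial_to_val = {a.serial: v for a, v in zip(atoms, per_atom)}
    for r in structure.residues:
        val = float(sum(serial_to_val.get(a.serial, 0.0) for a in r.atoms))
        sasa[r.residue_key] = val
        r.sasa = val
    return sasa


# ---------------------------------------------------------------------------
# Output

def interactions_to_tsv(interactions: Iterable[Interaction]) -> str:
    """Interaction list as TSV (kind, chain/resnum/atom x2, distance, bars)."""
    lines = ["kind\tchain_a\tresnum_a\tatom_a\tchain_b\tresnum_b\tatom_b\tdistance\tbars"]
    for iv in interactions:
        a, b = iv.atom_a, iv.atom_b
        lines.append("\t".join([
            iv.kind.value, a.residue_key[0], str(a.residue_key[1]), a.name,
            b.residue_key[0], str(b.residue_key[1]), b.name,
            f"{iv.distance():.3f}", str(iv.bars)]))
    return "\n".join(lines) + "\n"
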