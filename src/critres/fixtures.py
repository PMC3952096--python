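"""Self-contained test inputs: toy structures, random body-bar graphs,
synthetic rank files, and the encoded benchmark tables.

The toy generator emits small poly-alanine chains with standard bond
geometry whose stabilizing interactions are *planted*: carbonyl oxygens are
aimed so that a chosen set of O(i)...N(i+2) contacts falls safely inside the
hydrogen-bond cutoff (locking the intervening phi/psi torsions into a rigid
backbone segment), and C-beta atoms of chosen residue pairs are aimed at each
other to create hydrophobic tethers. Every generated structure is validated
by running the actual detectors: the detected noncovalent interaction set
must equal the planted one, otherwise generation fails loudly.

The ``two_domain_hinge`` geometry rigidifies two backbone segments but skips
one backbone contact at the junction per planted tether, leaving exactly as
many free phi/psi torsions as the bridging tethers remove: the wild-type
assembly is rigid with no redundancy, so an in-silico mutation of any
tether-bearing residue (and only those) disconnects the two rigid domains
and shrinks the largest rigid body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mechanical_model import BodyBarGraph
from .structure_model import (
    detect_covalent_bonds,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
    read_structure,
)

__all__ = [
    "ToySpec",
    "ToyStructure",
    "PlantingError",
    "make_toy_structure",
    "make_toy",
    "random_body_bar_graph",
    "synthetic_rank_file",
    "paper_tables",
]

FIXTURE_VERSION = "1.0"

GEOMETRIES = ("extended", "helix_like", "two_domain_hinge")

# backbone internal coordinates (A / degrees)
_BOND = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231, ca_cb=1.53)
_TORSIONS = {
    "extended": (-135.0, 135.0),
    # compact coil: C(i)..N(i+2) ~4 A with room to aim the carbonyl oxygen,
    # and CA pairs 3-4 residues apart within C-beta bridging reach
    "helix_like": (-10.0, -110.0),
    "two_domain_hinge": (-10.0, -110.0),
}
# junction torsions that swing the second domain into C-beta bridging reach
# while keeping the corridor between the domains sterically open; candidates
# are tried in order until one passes the planting validation
_GAP_TORSIONS = {
    1: [[(-150.0, 90.0)], [(-150.0, 60.0)], [(-150.0, 120.0)],
        [(-120.0, 120.0)], [(-30.0, -120.0)], [(0.0, -150.0)]],
    2: [[(-90.0, 150.0), (90.0, 0.0)], [(-120.0, 120.0), (120.0, 30.0)],
        [(-90.0, -180.0), (60.0, 0.0)], [(-60.0, -120.0), (0.0, -120.0)],
        [(-120.0, 120.0), (150.0, -60.0)], [(-90.0, 120.0), (120.0, -90.0)]],
}
_HB_TARGET = (2.7, 3.1)     # planted O..N distance window (cutoff 3.5)
_TETHER_TARGET = (2.7, 3.4)  # planted CB..CB distance window (cutoff 3.65)


class PlantingError(ValueError):
    """Requested interactions cannot be planted in the requested geometry."""


@dataclass(frozen=True)
class ToySpec:
    n_residues: int
    geometry: str = "extended"
    n_hbonds: int = 0
    n_tethers: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise PlantingError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 1 or self.n_hbonds < 0 or self.n_tethers < 0:
            raise PlantingError("counts must be non-negative, n_residues >= 1")


@dataclass
class ToyStructure:
    spec: ToySpec
    pdb_text: str
    planted_hbonds: list        # [(donor resnum, acceptor resnum)] 1-based
    planted_tethers: list       # [(resnum, resnum)] 1-based
    tether_anchors: list        # tether-bearing resnums (domain split points)
    junction: Optional[int]     # first free-pivot residue (two_domain_hinge)
    version: str = FIXTURE_VERSION


# -- internal geometry helpers ----------------------------------------------

def _nerf(a, b, c, bond, angle_deg, dih_deg):
    """Natural-extension placement of an atom from three predecessors."""
    ang, dih = math.radians(angle_deg), math.radians(dih_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(dih),
                  bond * math.sin(ang) * math.sin(dih)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _fib_dirs(m: int = 400) -> np.ndarray:
    i = np.arange(m) + 0.5
    phi = math.pi * (3 - math.sqrt(5)) * i
    z = 1 - 2 * i / m
    r = np.sqrt(np.clip(1 - z * z, 0, 1))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_DIRS = _fib_dirs()


def _place_oxygen(c_pos, target_n, obstacles, other_n, planted: bool):
    """Search the sphere of radius 1.231 around C for an oxygen position.

    Planted: 2.7-3.1 A from the target amide nitrogen, > 3.6 A from every
    other nitrogen, > 1.97 A from other heavy atoms. Unplanted: the same
    without a target.
    """
    cands = c_pos + _BOND["c_o"] * _DIRS
    best, best_score = None, -np.inf
    for o in cands:
        dh = np.min(np.linalg.norm(obstacles - o, axis=1)) if len(obstacles) else 9.0
        if dh < 1.97:
            continue
        dn = np.min(np.linalg.norm(other_n - o, axis=1)) if len(other_n) else 9.0
        if dn < 3.6:
            continue
        if planted:
            dt = float(np.linalg.norm(o - target_n))
            if not (_HB_TARGET[0] <= dt <= _HB_TARGET[1]):
                continue
        score = min(dh - 1.97, dn - 3.6)
        if score > best_score:
            best, best_score = o, score
    return best


def _place_cb(ca_pos, obstacles, far_cb, target=None, aim=None):
    """Search the sphere of radius 1.53 around CA for a C-beta position.

    Keeps >= 1.97 A from other heavy atoms and > 3.75 A from side-chain
    carbons that must not tether; with ``target`` the position lands inside
    the planted-tether window, with ``aim`` it gets as close as feasible to
    the aim point (so partner C-betas can reach it).
    """
    cands = ca_pos + _BOND["ca_cb"] * _DIRS
    best, best_score = None, -np.inf
    for cb in cands:
        dh = np.min(np.linalg.norm(obstacles - cb, axis=1)) if len(obstacles) else 9.0
        if dh < 1.97:
            continue
        dcb = np.min(np.linalg.norm(far_cb - cb, axis=1)) if len(far_cb) else 9.0
        if dcb < 3.75:
            continue
        if target is not None:
            dt = float(np.linalg.norm(cb - target))
            if not (_TETHER_TARGET[0] <= dt <= _TETHER_TARGET[1]):
                continue
            score = min(dh - 1.97, dcb - 3.75)
        elif aim is not None:
            score = -float(np.linalg.norm(cb - aim))
        else:
            score = min(dh - 1.97, dcb - 3.75)
        if score > best_score:
            best, best_score = cb, score
    return best


def _backbone(n: int, torsions):
    """Backbone N/CA/C from per-residue (phi, psi); a single pair is uniform."""
    if isinstance(torsions, tuple):
        torsions = [torsions] * n
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["n_ca"], 0.0, 0.0])]
    C = [_nerf(np.array([0.0, -1.0, 0.0]), N[0], CA[0], _BOND["ca_c"], 111.0, 0.0)]
    for i in range(1, n):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], _BOND["c_n"], 116.2,
                       torsions[i - 1][1]))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], _BOND["n_ca"], 121.7, 180.0))
        C.append(_nerf(C[i - 1], N[i], CA[i], _BOND["ca_c"], 111.0,
                       torsions[i][0]))
    return N, CA, C


def make_toy(spec: ToySpec) -> ToyStructure:
    """Generate a toy structure with planted, detector-validated interactions.

    For ``two_domain_hinge`` the junction-torsion candidates are tried in
    order and the first geometry that passes the detector validation wins.
    """
    if spec.geometry != "two_domain_hinge":
        return _build_toy(spec, None)
    gap = spec.n_tethers
    if gap not in _GAP_TORSIONS:
        raise PlantingError(
            f"two_domain_hinge supports {sorted(_GAP_TORSIONS)} tethers, "
            f"not {spec.n_tethers}")
    last_error: Exception = None
    for gap_tors in _GAP_TORSIONS[gap]:
        for oxygens_first in (False, True):
            try:
                return _build_toy(spec, gap_tors, oxygens_first)
            except PlantingError as exc:
                last_error = exc
    raise PlantingError(
        f"no junction geometry accommodates {gap} bridging tethers in "
        f"{spec.n_residues} residues ({last_error})")


def _build_toy(spec: ToySpec, gap_tors, oxygens_first: bool = False) -> ToyStructure:
    n = spec.n_residues

    if spec.geometry == "extended":
        if spec.n_hbonds or spec.n_tethers:
            raise PlantingError(
                "extended geometry cannot host planted contacts; "
                "use helix_like or two_domain_hinge")
        planted_is: set = set()
        junction = None
        torsions = _TORSIONS["extended"]
    elif spec.geometry == "helix_like":
        if spec.n_hbonds > max(n - 2, 0):
            raise PlantingError(
                f"cannot plant {spec.n_hbonds} backbone contacts in {n} residues")
        if spec.n_tethers:
            raise PlantingError(
                "tethers are planted across the two_domain_hinge geometry")
        planted_is = set(range(spec.n_hbonds))
        junction = None
        torsions = _TORSIONS["helix_like"]
    else:  # two_domain_hinge
        gap = spec.n_tethers  # one free phi/psi pair per bridging tether
        if not (8 <= n <= 10):
            # short by design: the compact domains start wrapping into the
            # junction corridor beyond ~10 residues, and 10 residues already
            # give ~41 bodies, near the rigidity-matrix oracle's reach
            raise PlantingError(
                "two_domain_hinge supports 8 to 10 residues")
        if spec.n_hbonds:
            raise PlantingError(
                "two_domain_hinge plants its backbone contacts implicitly; "
                "set n_hbonds = 0")
        junction = n // 2
        # the junction residues get their own torsions, and the backbone
        # contacts that would lock them are skipped: 2*gap free torsions
        planted_is = set(range(n - 2)) - set(range(junction - 1, junction + gap - 1))
        torsions = [_TORSIONS["two_domain_hinge"]] * n
        for g, tors in enumerate(gap_tors):
            torsions[junction + g] = tors

    N, CA, C = _backbone(n, torsions)
    CB = [_nerf(C[i], N[i], CA[i], _BOND["ca_cb"], 110.4, -122.0)
          for i in range(n)]

    # tether pairs bridge the junction at fixed junction-relative positions
    # (the base residue just past the gap reaches back across it)
    if spec.geometry == "two_domain_hinge":
        j, gap = junction, spec.n_tethers
        base = j + gap
        partners = [j - 3] if gap == 1 else [j - 3, j - 2]
        tether_pairs = [(a, base) for a in partners]
    else:
        tether_pairs = []
    tether_set = {frozenset(pair) for pair in tether_pairs}

    def replace_cb(r: int, target=None, aim=None) -> None:
        obstacles = np.array(
            [q for j2 in range(n) for q in (N[j2], CA[j2], C[j2])
             if not (j2 == r and q is CA[j2])]
            + [CB[j2] for j2 in range(n) if j2 != r] + O)
        far_cb = np.array(
            [CB[j2] for j2 in range(n)
             if abs(j2 - r) >= 2 and frozenset((j2, r)) not in tether_set])
        cb = _place_cb(CA[r], obstacles, far_cb, target=target, aim=aim)
        if cb is None:
            raise PlantingError(f"no feasible C-beta placement at residue {r + 1}")
        CB[r] = cb

    O: list = []

    def place_oxygens() -> None:
        for i in range(n):
            obstacles = np.array(
                [p for j in range(n) for p in (N[j], CA[j], C[j], CB[j])
                 if not (j == i and p is C[j])] + O)
            planted = i in planted_is
            if planted:
                other_n = np.array([N[j] for j in range(n)
                                    if j not in (i, i + 1, i + 2)])
                target = N[i + 2]
            else:
                other_n = np.array([N[j] for j in range(n) if j not in (i, i + 1)])
                target = None
            o = _place_oxygen(C[i], target, obstacles, other_n, planted)
            if o is None:
                raise PlantingError(
                    f"no feasible carbonyl-oxygen placement at residue {i + 1}")
            O.append(o)

    def place_cbetas() -> None:
        if not tether_pairs:
            return
        replace_cb(base, aim=np.mean([CA[a] for a in partners], axis=0))
        for a in partners:
            replace_cb(a, target=CB[base])

    # the carbonyl oxygens and the re-aimed C-betas compete for the space
    # around the junction; either placement order may be the feasible one
    if oxygens_first:
        place_oxygens()
        place_cbetas()
    else:
        place_cbetas()
        place_oxygens()

    # seed only re-poses the rigid structure: rotation + translation
    rng = np.random.default_rng(spec.seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    t = rng.uniform(-5, 5, size=3)

    lines = []
    serial = 0
    for i in range(n):
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]),
                          ("O", O[i]), ("CB", CB[i])):
            serial += 1
            xx, yy, zz = R @ pos + t
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{i + 1:4d}    "
                f"{xx:8.3f}{yy:8.3f}{zz:8.3f}  1.00  0.00           {name[0]}")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    toy = ToyStructure(
        spec=spec,
        pdb_text=pdb_text,
        planted_hbonds=sorted((i + 3, i + 1) for i in planted_is),
        planted_tethers=sorted((min(a, p) + 1, max(a, p) + 1)
                               for a, p in tether_pairs),
        tether_anchors=sorted({r + 1 for pair in tether_pairs for r in pair}),
        junction=junction + 1 if junction is not None else None,
    )
    _validate_planting(toy)
    return toy


def _validate_planting(toy: ToyStructure) -> None:
    """The detectors must find exactly the planted noncovalent interactions."""
    s = read_structure(toy.pdb_text, name="toy")
    cov = detect_covalent_bonds(s)
    n = toy.spec.n_residues
    expected_cov = 5 * n - 1  # N-CA, CA-C, C-O, CA-CB per residue + peptides
    if len(cov) != expected_cov:
        raise PlantingError(
            f"covalent detection found {len(cov)} bonds, expected {expected_cov}")
    hb = detect_hydrogen_bonds(s, covalent=cov)
    got_hb = sorted((max(iv.atom_a.residue_key[1], iv.atom_b.residue_key[1]),
                     min(iv.atom_a.residue_key[1], iv.atom_b.residue_key[1]))
                    for iv in hb)
    if got_hb != toy.planted_hbonds:
        raise PlantingError(
            f"hydrogen bonds {got_hb} differ from planted {toy.planted_hbonds}")
    th = detect_hydrophobic_tethers(s)
    got_th = sorted(tuple(sorted((iv.atom_a.residue_key[1],
                                  iv.atom_b.residue_key[1]))) for iv in th)
    if got_th != toy.planted_tethers:
        raise PlantingError(
            f"tethers {got_th} differ from planted {toy.planted_tethers}")


def make_toy_structure(spec: ToySpec) -> str:
    """PDB text of the validated toy structure."""
    return make_toy(spec).pdb_text


# ---------------------------------------------------------------------------
# Random body-bar multigraphs

def random_body_bar_graph(n: int, edge_density: float = 0.5,
                          max_mult: int = 6, seed: int = 0) -> BodyBarGraph:
    """Erdos-Renyi pair selection with uniform bar multiplicity 1..max_mult."""
    if n < 1:
        raise ValueError("need n >= 1 bodies")
    rng = np.random.default_rng(seed)
    g = BodyBarGraph(n_bodies=n)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_density:
                g.add_edge(i, j, int(rng.integers(1, max_mult + 1)), "random")
    return g


# ---------------------------------------------------------------------------
# Synthetic rank files

def synthetic_rank_file(n: int, conserved_fraction: float, seed: int = 0) -> dict:
    """Rank files (both dialects) with a planted well-conserved subset.

    The planted residues get low ranks, the rest high ranks, separated enough
    that the positive-score rule recovers exactly the planted set. A zero
    fraction degenerates to all-equal ranks (standard-deviation zero).
    Returns ``{"tsv": ..., "et_server": ..., "planted": [resnums]}``.
    """
    if n < 1:
        raise ValueError("need n >= 1 residues")
    if not (0.0 <= conserved_fraction <= 1.0):
        raise ValueError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(round(n * conserved_fraction))
    resnums = list(range(1, n + 1))
    planted = sorted(rng.choice(resnums, size=k, replace=False).tolist()) if k else []
    ranks = {}
    for r in resnums:
        if k == 0:
            ranks[r] = 50.0
        elif r in planted:
            ranks[r] = float(rng.uniform(1.0, 5.0))
        else:
            ranks[r] = float(rng.uniform(60.0, 100.0))
    tsv = "\n".join(f"{r}\t{ranks[r]:.3f}" for r in resnums) + "\n"
    et = ["% synthetic evolutionary-trace rank file",
          f"% {n} residues, version {FIXTURE_VERSION}",
          "%  align  res  type  rank"]
    for i, r in enumerate(resnums, 1):
        et.append(f" {i:5d} {r:5d}  ALA  {ranks[r]:8.3f}")
    return {"tsv": tsv, "et_server": "\n".join(et) + "\n", "planted": planted,
            "ranks": ranks}


# ---------------------------------------------------------------------------
# Encoded benchmark tables (glycine/alanine mutation study)
#
# Transcribed digit-for-digit from the published comparison of conservation
# and rigidity detections; used by the reporting layer's tests and the
# acceptance script. Row counts are checked at access time.

# 42 proteins, mutations to glycine:
# (pdb, n_residues, %cons, %rig, %both, %non, %match, %cons_only, %rig_only)
_TABLE1 = [
    ("1aho", 64, 50.0, 25.0, 15.6, 40.6, 56.3, 34.4, 9.4),
    ("1kiv", 80, 52.5, 16.3, 13.8, 42.5, 56.3, 38.8, 2.5),
    ("1r69", 63, 46.0, 6.3, 3.2, 50.8, 54.0, 42.9, 3.2),
    ("1uln", 82, 41.5, 19.5, 3.7, 42.7, 46.3, 37.8, 15.9),
    ("1wvn", 74, 52.7, 8.1, 5.4, 44.6, 50.0, 47.3, 2.7),
    ("2era", 62, 41.9, 29.0, 11.3, 40.3, 51.6, 30.6, 17.7),
    ("3p7k", 45, 88.9, 8.9, 8.9, 11.1, 20.0, 80.0, 0.0),
    ("1b9w", 91, 64.8, 18.7, 16.5, 33.0, 49.5, 48.4, 2.2),
    ("1mul", 90, 47.8, 7.8, 4.4, 33.3, 37.8, 43.3, 3.3),
    ("1f94", 63, 66.7, 30.2, 17.5, 20.6, 38.1, 49.2, 12.7),
    ("1sif", 71, 56.3, 15.5, 9.9, 38.0, 47.9, 46.5, 5.6),
    ("1x3o", 80, 56.3, 10.0, 6.3, 40.0, 46.3, 50.0, 3.8),
    ("2igd", 61, 55.7, 21.3, 16.4, 39.3, 55.7, 39.3, 4.9),
    ("2qt4", 95, 53.7, 5.3, 2.1, 43.2, 45.3, 51.6, 3.2),
    ("3gbl", 97, 55.7, 35.1, 24.7, 34.0, 58.8, 30.9, 10.3),
    ("1cdz", 96, 52.1, 16.7, 10.4, 41.7, 52.1, 41.7, 6.3),
    ("1mzl", 93, 48.4, 4.3, 1.1, 48.4, 49.5, 47.3, 3.2),
    ("1snb", 64, 53.1, 20.3, 14.1, 40.6, 54.7, 39.1, 6.3),
    ("1vcc", 77, 51.9, 13.0, 7.8, 42.9, 50.6, 44.2, 5.2),
    ("2nls", 36, 63.9, 22.2, 19.4, 33.3, 52.8, 44.4, 2.8),
    ("2xkm", 46, 78.3, 6.5, 6.5, 21.7, 28.3, 71.7, 0.0),
    ("3k2t", 56, 50.0, 12.5, 10.7, 42.9, 53.6, 39.3, 1.8),
    ("1t2i", 96, 55.2, 13.5, 9.4, 40.6, 50.0, 45.8, 4.2),
    ("1yp5", 58, 56.9, 17.2, 8.6, 34.5, 43.1, 48.3, 8.6),
    ("2o37", 81, 56.8, 19.8, 12.3, 35.8, 48.1, 44.4, 7.4),
    ("1wkx", 43, 53.5, 27.9, 16.3, 34.9, 51.2, 37.2, 11.6),
    ("1ucs", 64, 54.7, 4.7, 1.6, 42.2, 43.8, 53.1, 3.1),
    ("1hpt", 56, 41.1, 23.2, 12.5, 48.2, 60.7, 28.6, 10.7),
    ("3cqt", 58, 50.0, 29.3, 22.4, 43.1, 65.5, 27.6, 6.9),
    ("1ug4", 60, 53.3, 25.0, 13.3, 35.0, 48.3, 40.0, 11.7),
    ("2ygs", 92, 59.8, 4.3, 2.2, 38.0, 40.2, 57.6, 2.2),
    ("1csp", 67, 56.7, 6.0, 6.0, 43.3, 49.3, 50.7, 0.0),
    ("1jzb", 66, 50.0, 27.3, 19.7, 42.4, 62.1, 30.3, 7.6),
    ("3llb", 81, 53.1, 29.6, 18.5, 35.8, 54.3, 34.6, 11.1),
    ("1ntn", 72, 44.4, 20.8, 9.7, 43.1, 52.8, 34.7, 11.1),
    ("1whp", 94, 54.3, 20.2, 16.0, 41.5, 57.4, 38.3, 4.3),
    ("2b8i", 77, 51.9, 11.7, 10.4, 46.8, 57.1, 41.6, 1.3),
    ("2pcy", 99, 44.4, 12.1, 5.1, 48.5, 53.5, 39.4, 7.1),
    ("2zeq", 78, 62.8, 20.5, 16.7, 33.3, 50.0, 46.2, 3.8),
    ("3lyw", 86, 31.4, 10.5, 4.7, 60.5, 65.1, 26.7, 5.8),
    ("1pft", 87, 47.1, 16.1, 5.7, 41.4, 47.1, 41.4, 10.3),
    ("2pko", 99, 49.5, 12.1, 7.1, 45.5, 52.5, 42.4, 5.1),
]

# residues correctly identified by only one method (top 5 rigidity-only,
# bottom 14 conservation-only): (pdb, wt_residue, hydrophobicity, ddg,
# change to LRB upon in-silico mutation to glycine)
_TABLE2 = [
    ("1stn", "D95", "none", -3.1, 5),
    ("1iob", "T9", "very", -2.6, 7),
    ("2rn2", "S68", "none", -2.4, 12),
    ("1rtb", "V16", "very", -1.18, 9),
    ("3mbp", "V8", "very", -1.0, 6),
    ("1stn", "L37", "very", -3.9, 0),
    ("1stn", "T62", "none", -3.4, 0),
    ("3mbp", "A276", "slight", -1.5, 0),
    ("2rn2", "A52", "slight", -2.7, 0),
    ("1ftg", "A84", "slight", -1.25, 0),
    ("1cto", "V45", "very", -1.9, 0),
    ("1stn", "L36", "very", -5.4, 0),
    ("1rtb", "V54", "very", -4.87, 0),
    ("1rtb", "P93", "none", -2.6, 0),
    ("1lz1", "P103", "none", -0.1, 0),
    ("1rtb", "P114", "none", -3.6, 0),
    ("1lz1", "P71", "none", -1.6, 0),
    ("1iob", "P97", "none", -1.2, 0),
    ("3ssi", "V13", "very", -9.3, 0),
]

# mutations to glycine vs experiment:
# (pdb, mutation, sasa, ddg, pct_lrb_decrease, cons_flag, label, partners)
_TABLE3 = [
    ("1bpi", "N43G", 0.0, -5.7, 1.39, "Yes", "True Positive", 0),
    ("1bpi", "Y35G", 14.74, -5.0, 0.0, "Yes", "True Positive", 2),
    ("1lz1", "V2G", 191.52, -2.3, 0.0, "No", "False Negative", 0),
    ("1lz1", "V74G", 156.35, -0.22, 0.0, "No", "False Negative", 1),
    ("1lz1", "V110G", 181.77, 0.48, 1.93, "No", "False positive", 0),
    ("1lz1", "P71G", 72.63, -1.6, 0.29, "Yes", "True positive", 1),
    ("1lz1", "P103G", 146.25, -0.1, 0.37, "Yes", "True positive", 0),
    ("2rn2", "K95G", 142.44, 1.7, 0.0, "No", "True Negative", 0),
]

# 29 alanine mutations of the 58-residue pancreatic trypsin inhibitor:
# (mutation, sasa, ddg, pct_lrb_decrease, cons_flag, label, partners)
_TABLE4 = [
    ("K46A", 177.11, 0.1, 0.0, "No", "False Negative", 2),
    ("R53A", 174.71, -0.1, 0.0, "Yes", "True Positive", 2),
    ("T54A", 68.66, -0.1, 1.3944223108, "No", "True Positive", 2),
    ("T32A", 114.38, -0.1, 0.0, "No", "False Negative", 2),
    ("E49A", 116.65, -0.2, 0.0, "No", "False Negative", 1),
    ("G56A", 20.42, -0.2, 0.0, "No", "False Negative", 2),
    ("G57A", 39.32, -0.2, 0.0, "No", "False Negative", 0),
    ("R17A", 211.65, -0.3, 0.0, "No", "False Negative", 5),
    ("K15A", 196.87, -0.4, 0.0, "No", "False Negative", 5),
    ("K41A", 105.59, -0.4, 0.0, "Yes", "True Positive", 2),
    ("D50A", 51.92, -0.4, 0.0, "No", "False Negative", 1),
    ("R42A", 167.75, -0.5, 3.5856573705, "No", "True Positive", 2),
    ("Q31A", 79.04, -1.0, 1.9920318725, "No", "True Positive", 1),
    ("G28A", 41.29, -1.0, 0.0, "No", "False Negative", 1),
    ("Y35A", 14.74, -1.1, 0.0, "Yes", "False Negative", 2),
    ("P13A", 70.66, -1.2, 0.0, "Yes", "True Positive", 4),
    ("Y10A", 73.8, -1.2, 0.0, "No", "False Negative", 1),
    ("V34A", 117.65, -1.2, 0.0, "No", "False Negative", 3),
    ("I18A", 98.24, -1.5, 0.0, "No", "False Negative", 4),
    ("S47A", 35.24, -1.6, 0.796812749, "Yes", "True Positive", 1),
    ("M52A", 122.96, -1.7, 0.0, "No", "False Negative", 2),
    ("G12A", 16.54, -1.8, 0.0, "No", "False Negative", 4),
    ("R20A", 36.99, -1.8, 12.9482071713, "Yes", "True Positive", 2),
    ("F22A", 21.02, -2.0, 2.5896414343, "Yes", "True Positive", 0),
    ("G36A", 0.25, -2.1, 0.0, "Yes", "True Positive", 4),
    ("I19A", 158.0, -2.1, 0.0, "No", "False Negative", 3),
    ("N24A", 35.71, -2.2, 2.7888446215, "Yes", "True Positive", 0),
    ("G37A", 36.14, -2.3, 0.0, "Yes", "True Positive", 4),
    ("N44A", 19.98, -3.3, 3.5856573705, "Yes", "True Positive", 2),
]

# alanine mutations of the acyl-CoA binding protein (2abd) and the major
# cold-shock protein (1csp): (pdb, mutation, sasa, ddg, pct, cons, label)
_TABLE5 = [
    ("2abd", "E67A", 99.97, -0.36, 0.0, "No", "False Negative"),
    ("1csp", "F17A", 57.18, -0.81, 4.33, "No", "True Positive"),
    ("2abd", "K54A", 49.09, -0.86, 1.98, "Yes", "True Positive"),
    ("1csp", "F27A", 70.65, -0.89, 0.0, "Yes", "True Positive"),
    ("1csp", "F15A", 50.5, -0.96, 2.96, "No", "True Positive"),
    ("2abd", "K32A", 63.06, -1.02, 1.18, "Yes", "True Positive"),
    ("2abd", "L25A", 15.81, -1.02, 3.76, "Yes", "True Positive"),
    ("2abd", "P44A", 49.62, -1.04, 3.06, "Yes", "True Positive"),
    ("2abd", "P19A", 5.59, -1.07, 0.0, "Yes", "True Positive"),
    ("2abd", "T35A", 51.06, -1.09, 0.69, "Yes", "True Positive"),
    ("2abd", "V77A", 8.94, -1.14, 0.59, "Yes", "True Positive"),
    ("2abd", "V12A", 8.78, -1.69, 2.37, "Yes", "True Positive"),
    ("2abd", "Y28A", 50.63, -2.47, 1.28, "Yes", "True Positive"),
    ("2abd", "L15A", 0.0, -3.1, 1.18, "Yes", "True Positive"),
    ("2abd", "Q33A", 1.59, -3.66, 0.99, "Yes", "True Positive"),
    ("2abd", "L80A", 3.15, -3.7, 3.26, "Yes", "True Positive"),
    ("2abd", "Y73A", 4.5, -4.83, 1.28, "Yes", "True Positive"),
]

_T1_COLS = ["pdb", "n_residues", "pct_cons_critical", "pct_rig_critical",
            "pct_both_critical", "pct_both_noncritical", "pct_total_match",
            "pct_cons_only", "pct_rig_only"]


def paper_tables() -> dict:
    """The encoded benchmark tables as pandas DataFrames.

    Keys: ``table1`` (42 per-protein agreement rows, glycine scan),
    ``table2`` (19 single-method detections), ``table3`` (8 glycine
    mutations vs ddG), ``table4`` (29 alanine mutations of the trypsin
    inhibitor), ``table5`` (17 alanine mutations of 2abd/1csp).
    Row-count checksums are verified on every call.
    """
    t1 = pd.DataFrame(_TABLE1, columns=_T1_COLS)
    t2 = pd.DataFrame(_TABLE2, columns=["pdb", "wt_residue", "hydrophobicity",
                                        "ddg", "lrb_change"])
    t3 = pd.DataFrame(_TABLE3, columns=["pdb", "mutation", "sasa", "ddg",
                                        "pct_decrease", "cons_critical",
                                        "label", "binding_partners"])
    t4 = pd.DataFrame(_TABLE4, columns=["mutation", "sasa", "ddg",
                                        "pct_decrease", "cons_critical",
                                        "label", "binding_partners"])
    t4.insert(0, "pdb", "1bpi")
    t5 = pd.DataFrame(_TABLE5, columns=["pdb", "mutation", "sasa", "ddg",
                                        "pct_decrease", "cons_critical",
                                        "label"])
    counts = {"table1": 42, "table2": 19, "table3": 8, "table4": 29,
              "table5": 17}
    tables = {"table1": t1, "table2": t2, "table3": t3, "table4": t4,
              "table5": t5}
    for name, df in tables.items():
        if len(df) != counts[name]:
            raise AssertionError(
                f"{name} transcription checksum failed: {len(df)} rows, "
                f"expected {counts[name]}")
    return tables
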