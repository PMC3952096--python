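"""In-silico mutation to glycine or alanine by constraint removal.

Mutating a residue to glycine removes every hydrogen bond and hydrophobic
tether contributed by its side chain (C-beta and beyond) from the mechanical
model; mutation to alanine keeps C-beta's interactions and removes only those
of atoms beyond it. Covalent bonds are never removed and atoms are not
deleted, so the body topology of the model is preserved while constraints
drop out. The residue's criticality score is the percentage decrease of the
largest rigid body (LRB, in atoms) between the wild-type and mutant models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .mechanical_model import BarPolicy, build_bodies, build_graph, MechanicalModel
from .pebble_game import pebble_analyze
from .structure_model import Interaction, Structure

__all__ = ["MutationOutcome", "mutate_in_silico", "mutation_scan",
           "outcomes_to_tsv"]

# alanine retains C-beta and its hydrogens
_ALA_KEPT = ("CB", "HB", "HB1", "HB2", "HB3", "1HB", "2HB", "3HB")


@dataclass
class MutationOutcome:
    residue_key: tuple
    target: str                  # "GLY" or "ALA"
    lrb_wt: int                  # atoms in the wild-type largest rigid body
    lrb_mut: int
    pct_decrease: float          # 100 * (lrb_wt - lrb_mut) / lrb_wt
    lrb_change: int              # raw atom-count drop
    removed_interactions: int
    rigidity_critical: bool

    def __post_init__(self):
        if not (0.0 <= self.pct_decrease <= 100.0):
            raise ValueError("pct_decrease out of [0, 100]")


def _removed_for_target(atom, target: str) -> bool:
    if not atom.is_sidechain:
        return False
    if target == "ALA" and atom.name in _ALA_KEPT:
        return False
    return True


def mutate_in_silico(structure: Structure, interactions: Iterable[Interaction],
                     residue_key: tuple, target: str) -> list:
    """Return the interaction list with the residue's side-chain hydrogen
    bonds and hydrophobic tethers removed (GLY: C-beta and beyond; ALA:
    beyond C-beta). Covalent bonds always survive."""
    target = target.upper()
    if target not in ("GLY", "ALA"):
        raise ValueError(f"mutation target must be GLY or ALA, got {target!r}")
    residue = structure.residue(residue_key)  # KeyError if absent
    if residue.aa_type == "GLY":
        warnings.warn(f"residue {residue_key} is already glycine; nothing to remove")
    elif target == "ALA" and residue.aa_type == "ALA":
        warnings.warn(f"residue {residue_key} is already alanine; nothing to remove")

    kept = []
    for iv in interactions:
        if iv.is_covalent:
            kept.append(iv)
            continue
        hit = False
        for atom in (iv.atom_a, iv.atom_b):
            if atom.residue_key == residue_key and _removed_for_target(atom, target):
                hit = True
                break
        if not hit:
            kept.append(iv)
    return kept


def mutation_scan(structure: Structure, interactions: list,
                  targets: str = "GLY",
                  residue_keys: Optional[list] = None,
                  tau_r: float = 0.0,
                  bar_policy: Optional[BarPolicy] = None) -> list:
    """Mutate each residue in-silico, re-run the pebble game, and score it by
    the percentage decrease of the largest rigid body (atom count).

    ``rigidity_critical`` is pct_decrease > tau_r; the default tau_r = 0
    treats any strictly positive LRB decrease as a rigidity detection.
    """
    interactions = list(interactions)
    covalent = [iv for iv in interactions if iv.is_covalent]
    bodies = build_bodies(structure, covalent)
    wt_graph = build_graph(bodies, interactions, bar_policy)
    wt_model = MechanicalModel(structure, bodies, wt_graph, interactions)
    wt_result = pebble_analyze(wt_graph, model=wt_model)
    lrb_wt = wt_result.lrb_atoms

    if residue_keys is None:
        residue_keys = [r.residue_key for r in structure.residues]

    outcomes = []
    for key in residue_keys:
        reduced = mutate_in_silico(structure, interactions, key, targets)
        n_removed = len(interactions) - len(reduced)
        if n_removed == 0:
            lrb_mut = lrb_wt  # untouched model: no recomputation needed
        else:
            mut_graph = build_graph(bodies, reduced, bar_policy)
            mut_model = MechanicalModel(structure, bodies, mut_graph, reduced)
            lrb_mut = pebble_analyze(mut_graph, model=mut_model).lrb_atoms
        pct = 100.0 * (lrb_wt - lrb_mut) / lrb_wt if lrb_wt > 0 else 0.0
        outcomes.append(MutationOutcome(
            residue_key=key,
            target=targets.upper(),
            lrb_wt=lrb_wt,
            lrb_mut=lrb_mut,
            pct_decrease=pct,
            lrb_change=lrb_wt - lrb_mut,
            removed_interactions=n_removed,
            rigidity_critical=pct > tau_r,
        ))
    return outcomes


def outcomes_to_tsv(outcomes: list) -> str:
    lines = ["chain\tresnum\ticode\ttarget\tlrb_wt\tlrb_mut\tlrb_change\t"
             "pct_decrease\tremoved\tcritical"]
    for o in outcomes:
        cid, num, icode = o.residue_key
        lines.append(f"{cid}\t{num}\t{icode}\t{o.target}\t{o.lrb_wt}\t"
                     f"{o.lrb_mut}\t{o.lrb_change}\t{o.pct_decrease:.4f}\t"
                     f"{o.removed_interactions}\t{o.rigidity_critical}")
    return "\n".join(lines) + "\n"
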