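"""Body-bar-hinge mechanical model of a molecule.

A covalently bonded atom together with its neighbours forms a rigid body
(bond lengths plus bond-angle constraints leave no internal freedom), so two
bodies whose anchor atoms are bonded share exactly the two bonded atoms and
their common rotatable bond becomes a hinge: 5 parallel edges between the two
graph nodes. Locked covalent bonds (peptide, ring, sp2) contribute 6 edges,
hydrogen bonds and hydrophobic tethers contribute a configurable number of
bars (defaults 5 and 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .structure_model import Atom, Interaction, InteractionKind, Structure

__all__ = [
    "Body",
    "BodyBarGraph",
    "BarPolicy",
    "MechanicalModel",
    "ModelError",
    "build_bodies",
    "build_graph",
    "build_model",
    "graph_to_tsv",
    "graph_from_tsv",
]

logger = logging.getLogger(__name__)

MAX_PAIR_MULTIPLICITY = 6  # extra parallel bars are redundant in a (6,6) framework


class ModelError(ValueError):
    """Raised when the mechanical model cannot be constructed."""


@dataclass
class Body:
    id: int
    atom_ids: frozenset  # atom serials
    anchor_atom: int

    def __post_init__(self):
        if not self.atom_ids:
            raise ModelError(f"body {self.id} has no atoms")
        if self.anchor_atom not in self.atom_ids:
            raise ModelError(f"body {self.id}: anchor not among its atoms")


@dataclass
class BodyBarGraph:
    """Multigraph of rigid bodies and bars.

    ``edges`` keeps one record per interaction (body_a, body_b, multiplicity,
    provenance) so parallel contributions remain visible; the pebble game
    consumes :meth:`pair_multiplicities`, where the total number of parallel
    bars between one body pair is capped at 6 (excess bars are combinatorially
    redundant and trimmed, with a log note).
    """
    n_bodies: int
    edges: list = field(default_factory=list)  # (u, v, mult, provenance)

    def __post_init__(self):
        for u, v, m, _ in self.edges:
            if u == v:
                raise ModelError("self-loop in body-bar graph")
            if m < 1:
                raise ModelError("edge multiplicity must be >= 1")
            if not (0 <= u < self.n_bodies and 0 <= v < self.n_bodies):
                raise ModelError("edge endpoint out of range")

    def add_edge(self, u: int, v: int, mult: int, provenance: str = "") -> None:
        if u == v:
            raise ModelError("self-loop in body-bar graph")
        if mult < 1:
            raise ModelError("edge multiplicity must be >= 1")
        if not (0 <= u < self.n_bodies and 0 <= v < self.n_bodies):
            raise ModelError("edge endpoint out of range")
        self.edges.append((u, v, int(mult), provenance))

    def pair_multiplicities(self) -> dict:
        """Per-pair total multiplicity, capped at 6 bars."""
        totals: dict = {}
        for u, v, m, _ in self.edges:
            key = (min(u, v), max(u, v))
            totals[key] = totals.get(key, 0) + m
        for key, m in totals.items():
            if m > MAX_PAIR_MULTIPLICITY:
                logger.info("trimming %d parallel bars between bodies %s to %d",
                            m, key, MAX_PAIR_MULTIPLICITY)
                totals[key] = MAX_PAIR_MULTIPLICITY
        return totals

    @property
    def total_multiplicity(self) -> int:
        """Total bar count after the cap-at-6 trim."""
        return sum(self.pair_multiplicities().values())

    @property
    def raw_multiplicity(self) -> int:
        return sum(m for _, _, m, _ in self.edges)

    def parallel_edges(self, u: int, v: int) -> int:
        key = (min(u, v), max(u, v))
        return sum(m for a, b, m, _ in self.edges if (min(a, b), max(a, b)) == key)


@dataclass
class BarPolicy:
    hbond_bars: int = 5
    hydrophobic_bars: int = 2


@dataclass
class MechanicalModel:
    structure: Structure
    bodies: list
    graph: BodyBarGraph
    interactions: list

    def body_atoms(self, body_id: int) -> frozenset:
        return self.bodies[body_id].atom_ids

    def atom_union(self, body_ids: Iterable[int]) -> set:
        out: set = set()
        for b in body_ids:
            out |= self.bodies[b].atom_ids
        return out


def build_bodies(structure: Structure, covalent: list) -> list:
    """One body per non-terminal atom: the atom plus all covalent neighbours.

    Atoms with at most one bond do not generate their own body; they are
    absorbed into a neighbour's body. A bonded pair of terminal atoms forms a
    single two-atom body; an isolated atom gets a singleton body (warning).
    """
    import warnings

    neighbours: dict = {a.serial: set() for a in structure.atoms}
    for iv in covalent:
        if not iv.is_covalent:
            continue
        neighbours[iv.atom_a.serial].add(iv.atom_b.serial)
        neighbours[iv.atom_b.serial].add(iv.atom_a.serial)

    bodies: list = []
    has_own_body: set = set()
    for a in structure.atoms:
        nbrs = neighbours[a.serial]
        if len(nbrs) >= 2:
            bodies.append(Body(len(bodies),
                               frozenset({a.serial} | nbrs), a.serial))
            has_own_body.add(a.serial)

    # components made solely of terminal atoms: diatomics and isolated atoms
    covered = set()
    for b in bodies:
        covered |= b.atom_ids
    for a in structure.atoms:
        s = a.serial
        if s in covered:
            continue
        nbrs = neighbours[s]
        if not nbrs:
            warnings.warn(f"isolated atom {s} ({a.name}) gets a singleton body")
            bodies.append(Body(len(bodies), frozenset({s}), s))
            covered.add(s)
        else:
            other = min(nbrs)
            anchor = min(s, other)
            bodies.append(Body(len(bodies), frozenset({s, other}), anchor))
            covered.add(s)
            covered.add(other)
    return bodies


def _anchor_index(bodies: list) -> dict:
    return {b.anchor_atom: b.id for b in bodies}


def _containing_bodies(bodies: list) -> dict:
    members: dict = {}
    for b in bodies:
        for s in b.atom_ids:
            members.setdefault(s, []).append(b.id)
    return members


def _body_for_atom(serial: int, anchors: dict, members: dict) -> int:
    """The body anchored at the atom if any, else the lowest-id containing body."""
    if serial in anchors:
        return anchors[serial]
    cands = members.get(serial)
    if not cands:
        raise ModelError(f"interaction atom {serial} not covered by any body")
    return min(cands)


def build_graph(bodies: list, interactions: list,
                bar_policy: Optional[BarPolicy] = None) -> BodyBarGraph:
    """Translate interactions into the body-bar multigraph.

    Rotatable covalent bonds become 5 parallel edges between the two bodies
    sharing the bond, locked bonds 6; hydrogen bonds and tethers connect the
    bodies anchored at their endpoint atoms with the policy's bar count.
    """
    policy = bar_policy or BarPolicy()
    anchors = _anchor_index(bodies)
    members = _containing_bodies(bodies)
    g = BodyBarGraph(n_bodies=len(bodies))
    for iv in interactions:
        sa, sb = iv.atom_a.serial, iv.atom_b.serial
        ba = _body_for_atom(sa, anchors, members)
        bb = _body_for_atom(sb, anchors, members)
        if iv.kind is InteractionKind.COVALENT_ROTATABLE:
            mult = 5
        elif iv.kind is InteractionKind.COVALENT_LOCKED:
            mult = 6
        elif iv.kind is InteractionKind.HBOND:
            mult = policy.hbond_bars
        else:
            mult = policy.hydrophobic_bars
        if ba == bb:
            continue  # both endpoints inside one body: constraint already implied
        g.add_edge(min(ba, bb), max(ba, bb), mult, iv.kind.value)
    g.edges.sort()
    return g


def build_model(structure: Structure, interactions: list,
                bar_policy: Optional[BarPolicy] = None) -> MechanicalModel:
    """Convenience wrapper: bodies + graph from a full interaction list."""
    covalent = [iv for iv in interactions if iv.is_covalent]
    bodies = build_bodies(structure, covalent)
    graph = build_graph(bodies, interactions, bar_policy)
    return MechanicalModel(structure, bodies, graph, list(interactions))


def graph_to_tsv(graph: BodyBarGraph) -> str:
    lines = [f"# n_bodies\t{graph.n_bodies}",
             "body_a\tbody_b\tmultiplicity\tkind"]
    for u, v, m, kind in graph.edges:
        lines.append(f"{u}\t{v}\t{m}\t{kind}")
    return "\n".join(lines) + "\n"


def graph_from_tsv(text: str) -> BodyBarGraph:
    n_bodies = None
    edges = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("# n_bodies"):
            n_bodies = int(line.split("\t")[1])
            continue
        if line.startswith("body_a"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ModelError(f"line {ln}: expected body_a, body_b, multiplicity")
        u, v, m = int(parts[0]), int(parts[1]), int(parts[2])
        kind = parts[3] if len(parts) > 3 else ""
        edges.append((u, v, m, kind))
    if n_bodies is None:
        n_bodies = 1 + max((max(u, v) for u, v, _, _ in edges), default=-1)
    return BodyBarGraph(n_bodies=n_bodies, edges=edges)
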