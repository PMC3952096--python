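"""Generic rigidity of body-bar multigraphs via the (6,6) pebble game.

A rigid body in 3-space has 6 degrees of freedom, so each graph node starts
with 6 pebbles. An edge (a generic bar between two bodies) is independent iff
7 pebbles can be gathered on its endpoints before insertion; inserting it
consumes one pebble and orients the edge. By Tay's theorem the independent
edge set is exactly a maximal (6,6)-sparse subgraph, so the count of
independent edges equals the generic rank of the body-bar framework.

Rigid components (maximal sets of mutually immobile bodies) are maintained
with the standard detection step: after an independent insertion that leaves
exactly 6 pebbles collectable on the edge's endpoints, every vertex that
cannot reach a free pebble (other than those 6) belongs to the new component.
For l = k = 6 maximal components are vertex-disjoint, so they form a
partition, tracked here with union-find.

:func:`rigidity_matrix_oracle` provides an independent linear-algebra check:
it realizes the multigraph as generic bars in 3-space, builds the rigidity
matrix row by row, and reads degrees of freedom and pairwise rigidity off the
nullspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import null_space

from .mechanical_model import BodyBarGraph, MechanicalModel

__all__ = [
    "RigidityResult",
    "OracleResult",
    "pebble_analyze",
    "largest_rigid_body",
    "rigidity_matrix_oracle",
]

K = 6  # pebbles per body (3D body-bar)
L = 6  # sparsity offset; an edge needs L+1 collectable pebbles


@dataclass
class RigidityResult:
    components: list            # list of frozensets of body ids (a partition)
    independent_edges: int
    redundant_edges: int
    free_dof: int               # 6n - 6 - independent_edges (n >= 1)
    lrb_atoms: Optional[int] = None  # set when a MechanicalModel is supplied

    @property
    def largest_component(self) -> frozenset:
        if not self.components:
            return frozenset()
        return max(self.components, key=lambda c: (len(c), -min(c)))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if ra > rb:
                ra, rb = rb, ra
            self.parent[rb] = ra


class _PebbleGame:
    """Directed-graph state of the (6,6) pebble game."""

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [K] * n
        self.out = [dict() for _ in range(n)]  # v -> {w: directed multiplicity}
        self.uf = _UnionFind(n)
        self.independent = 0
        self.redundant = 0

    # -- pebble search ------------------------------------------------------

    def _augment(self, u: int, v: int) -> bool:
        """Move one free pebble from outside {u, v} onto u or v, if possible."""
        seen = [False] * self.n
        seen[u] = seen[v] = True
        parent = {}
        stack = [u, v]
        found = -1
        while stack:
            x = stack.pop()
            for w, mult in self.out[x].items():
                if mult <= 0 or seen[w]:
                    continue
                seen[w] = True
                parent[w] = x
                if self.pebbles[w] > 0:
                    found = w
                    stack = []
                    break
                stack.append(w)
        if found < 0:
            return False
        # reverse the path: the pebble walks back to u or v
        w = found
        self.pebbles[w] -= 1
        while w in parent:
            x = parent[w]
            self.out[x][w] -= 1
            if self.out[x][w] == 0:
                del self.out[x][w]
            self.out[w][x] = self.out[w].get(x, 0) + 1
            w = x
        self.pebbles[w] += 1
        return True

    def _gather(self, u: int, v: int, target: int) -> bool:
        while self.pebbles[u] + self.pebbles[v] < target:
            if not self._augment(u, v):
                return False
        return True

    # -- component detection ------------------------------------------------

    def _mark_component(self, u: int, v: int) -> None:
        """Union every vertex that cannot reach a free pebble outside {u, v}."""
        free = [w for w in range(self.n)
                if self.pebbles[w] > 0 and w not in (u, v)]
        # reverse reachability: who has a directed path to a free vertex?
        in_adj = [[] for _ in range(self.n)]
        for x in range(self.n):
            for w, mult in self.out[x].items():
                if mult > 0:
                    in_adj[w].append(x)
        can_reach = [False] * self.n
        stack = list(free)
        for f in free:
            can_reach[f] = True
        while stack:
            w = stack.pop()
            for x in in_adj[w]:
                if not can_reach[x]:
                    can_reach[x] = True
                    stack.append(x)
        members = [w for w in range(self.n) if not can_reach[w]]
        for w in members[1:]:
            self.uf.union(members[0], w)

    # -- edge insertion -----------------------------------------------------

    def insert(self, u: int, v: int, mult: int) -> None:
        for _ in range(mult):
            if self.uf.find(u) == self.uf.find(v):
                self.redundant += 1
                continue
            if not self._gather(u, v, L + 1):
                self.redundant += 1
                continue
            if self.pebbles[u] == 0:
                u, v = v, u
            self.pebbles[u] -= 1
            self.out[u][v] = self.out[u].get(v, 0) + 1
            self.independent += 1
            # component check: can a 7th pebble still be collected?
            if self.pebbles[u] + self.pebbles[v] <= L and not self._augment(u, v):
                self._mark_component(u, v)


def pebble_analyze(graph: BodyBarGraph,
                   model: Optional[MechanicalModel] = None) -> RigidityResult:
    """Run the (6,6) pebble game on a body-bar multigraph.

    Parallel multiplicity between one body pair is consumed capped at 6 (see
    :meth:`BodyBarGraph.pair_multiplicities`); the result does not depend on
    the order in which edges are inserted.
    """
    n = graph.n_bodies
    if n == 0:
        return RigidityResult([], 0, 0, 0, 0 if model is not None else None)
    game = _PebbleGame(n)
    for (u, v), mult in sorted(graph.pair_multiplicities().items()):
        game.insert(u, v, mult)
    classes: dict = {}
    for w in range(n):
        classes.setdefault(game.uf.find(w), []).append(w)
    components = sorted((frozenset(m) for m in classes.values()),
                        key=lambda c: (-len(c), min(c)))
    result = RigidityResult(
        components=components,
        independent_edges=game.independent,
        redundant_edges=game.redundant,
        free_dof=K * n - 6 - game.independent,
    )
    if model is not None:
        result.lrb_atoms = largest_rigid_body(result, model)
    return result


def largest_rigid_body(result: RigidityResult,
                       model: Optional[MechanicalModel] = None) -> int:
    """Size of the largest rigid component.

    Without a mechanical model the size is counted in bodies; with one, in
    atoms of the union of the component's bodies. Ties go to the component
    whose smallest body id is smallest.
    """
    if not result.components:
        return 0
    if model is None:
        best = max(result.components, key=lambda c: (len(c), -min(c)))
        return len(best)
    best_atoms = -1
    best_minid = None
    for comp in result.components:
        n_atoms = len(model.atom_union(comp))
        minid = min(comp)
        if n_atoms > best_atoms or (n_atoms == best_atoms and minid < best_minid):
            best_atoms, best_minid = n_atoms, minid
    return best_atoms


# ---------------------------------------------------------------------------
# Independent oracle: explicit rigidity matrix at a generic placement

@dataclass
class OracleResult:
    free_dof: int
    rigid_pairs: np.ndarray     # (n, n) boolean, mutual rigidity
    components: list = field(default_factory=list)


def rigidity_matrix_oracle(graph: BodyBarGraph, seed: int = 0,
                           max_bodies: int = 50, n_trials: int = 3,
                           tol: float = 1e-8) -> OracleResult:
    """Brute-force rigidity via a random generic bar realization.

    Every unit of edge multiplicity becomes one bar between random points p on
    body i and q on body j; with body velocity screws (omega, t) the bar
    contributes the row ((t_i + omega_i x p) - (t_j + omega_j x q)) . (p - q)
    = 0. Degrees of freedom = nullity - 6 (the trivial motions); bodies are
    mutually rigid iff their screws agree in every nullspace vector. The
    computation is repeated at ``n_trials`` seeds and the generic
    (maximal-rank) outcome kept.
    """
    n = graph.n_bodies
    if n > max_bodies:
        raise ValueError(f"oracle limited to {max_bodies} bodies (got {n})")
    if n == 0:
        return OracleResult(0, np.zeros((0, 0), dtype=bool), [])

    pairs = sorted(graph.pair_multiplicities().items())
    best = None
    for trial in range(n_trials):
        rng = np.random.default_rng(seed + trial)
        centers = rng.normal(scale=3.0, size=(n, 3))
        rows = []
        for (i, j), mult in pairs:
            for _ in range(mult):
                p = centers[i] + rng.normal(size=3)
                q = centers[j] + rng.normal(size=3)
                d = p - q
                row = np.zeros(6 * n)
                row[6 * i: 6 * i + 3] = np.cross(p, d)
                row[6 * i + 3: 6 * i + 6] = d
                row[6 * j: 6 * j + 3] -= np.cross(q, d)
                row[6 * j + 3: 6 * j + 6] -= d
                rows.append(row)
        if rows:
            a = np.array(rows)
            ns = null_space(a, rcond=1e-10)
            rank = 6 * n - ns.shape[1]
        else:
            ns = np.eye(6 * n)
            rank = 0
        if best is None or rank > best[0]:
            best = (rank, ns)
    rank, ns = best
    free_dof = (6 * n - rank) - 6

    rigid = np.zeros((n, n), dtype=bool)
    blocks = ns.reshape(n, 6, -1)  # per-body screws across the nullspace basis
    for i in range(n):
        rigid[i, i] = True
        for j in range(i + 1, n):
            same = np.max(np.abs(blocks[i] - blocks[j])) < tol if ns.shape[1] else True
            rigid[i, j] = rigid[j, i] = same

    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if rigid[i, j]:
                uf.union(i, j)
    classes: dict = {}
    for w in range(n):
        classes.setdefault(uf.find(w), []).append(w)
    components = sorted((frozenset(m) for m in classes.values()),
                        key=lambda c: (-len(c), min(c)))
    return OracleResult(free_dof=free_dof, rigid_pairs=rigid,
                        components=components)
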