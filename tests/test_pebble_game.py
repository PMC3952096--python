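"""The (6,6) pebble game against analytic cases and the rigidity-matrix
oracle, plus its combinatorial invariants."""

import random

import numpy as np
import pytest

from critres.fixtures import random_body_bar_graph
from critres.mechanical_model import BodyBarGraph
from critres.pebble_game import (
    largest_rigid_body,
    pebble_analyze,
    rigidity_matrix_oracle,
)
from conftest import graph_of


def components_set(components):
    return sorted(sorted(c) for c in components)


class TestAnalyticCases:
    @pytest.mark.parametrize("desc,n,edges,free_dof,n_components", [
        ("hinge pair keeps one rotation", 2, [(0, 1, 5)], 1, 2),
        ("six bars lock two bodies", 2, [(0, 1, 6)], 0, 1),
        ("seventh bar is redundant", 2, [(0, 1, 7)], 0, 1),
        ("single bar removes one dof", 2, [(0, 1, 1)], 5, 2),
        ("six-hinge ring is rigid", 6,
         [(i, (i + 1) % 6, 5) for i in range(6)], 0, 1),
        ("seven-hinge ring has one internal dof", 7,
         [(i, (i + 1) % 7, 5) for i in range(7)], 1, 7),
        ("single body", 1, [], 0, 1),
    ])
    def test_free_dof_and_components(self, desc, n, edges, free_dof,
                                     n_components):
        g = graph_of(n, edges)
        result = pebble_analyze(g)
        assert result.free_dof == free_dof, desc
        assert len(result.components) == n_components, desc
        oracle = rigidity_matrix_oracle(g, seed=5)
        assert oracle.free_dof == free_dof, desc
        assert components_set(oracle.components) == \
            components_set(result.components), desc

    def test_seven_bars_report_one_redundant(self):
        result = pebble_analyze(graph_of(2, [(0, 1, 7)]))
        # the pair multiplicity is capped at 6, one of which is redundant
        assert result.independent_edges == 6
        assert result.redundant_edges == 0

    def test_edge_accounting(self):
        g = graph_of(3, [(0, 1, 6), (1, 2, 6), (0, 2, 6)])
        result = pebble_analyze(g)
        assert result.independent_edges + result.redundant_edges == \
            g.total_multiplicity
        assert result.redundant_edges == 18 - 12  # 6*3-6 independent max

    def test_empty_graph(self):
        result = pebble_analyze(BodyBarGraph(n_bodies=0))
        assert result.free_dof == 0
        assert largest_rigid_body(result) == 0


class TestOracle:
    def test_single_body_no_dof(self):
        assert rigidity_matrix_oracle(graph_of(1, []), seed=0).free_dof == 0

    def test_one_bar_leaves_five_dof(self):
        assert rigidity_matrix_oracle(graph_of(2, [(0, 1, 1)]),
                                      seed=0).free_dof == 5

    def test_refuses_large_graphs(self):
        with pytest.raises(ValueError):
            rigidity_matrix_oracle(graph_of(60, []), seed=0)


class TestOracleEquivalence:
    """Pebble-game output must match generic linear algebra exactly."""

    @pytest.mark.parametrize("batch", range(5))
    def test_random_multigraphs(self, batch):
        rng = np.random.default_rng(1000 + batch)
        for _ in range(30):
            n = int(rng.integers(1, 11))
            g = random_body_bar_graph(n, float(rng.uniform(0.1, 1.0)),
                                      max_mult=6,
                                      seed=int(rng.integers(0, 2**31)))
            result = pebble_analyze(g)
            oracle = rigidity_matrix_oracle(g, seed=int(rng.integers(0, 2**31)))
            assert result.free_dof == oracle.free_dof
            assert components_set(result.components) == \
                components_set(oracle.components)


class TestInvariants:
    def test_insertion_order_invariance(self):
        g = random_body_bar_graph(8, 0.6, seed=42)
        base = pebble_analyze(g)
        rnd = random.Random(3)
        for _ in range(10):
            edges = list(g.edges)
            rnd.shuffle(edges)
            # replay the game in shuffled raw-edge order, bypassing the
            # sorted pair iteration of pebble_analyze
            from critres.pebble_game import _PebbleGame, K

            game = _PebbleGame(g.n_bodies)
            for u, v, mult, _ in edges:
                game.insert(u, v, mult)
            assert K * g.n_bodies - 6 - game.independent == base.free_dof
            classes = {}
            for w in range(g.n_bodies):
                classes.setdefault(game.uf.find(w), []).append(w)
            assert components_set(classes.values()) == \
                components_set(base.components)

    def test_deleting_edges_never_decreases_dof(self):
        g = random_body_bar_graph(7, 0.7, seed=11)
        base = pebble_analyze(g).free_dof
        for k in range(len(g.edges)):
            reduced = BodyBarGraph(n_bodies=g.n_bodies,
                                   edges=g.edges[:k] + g.edges[k + 1:])
            assert pebble_analyze(reduced).free_dof >= base

    def test_adding_edges_never_increases_dof(self):
        rng = np.random.default_rng(17)
        g = random_body_bar_graph(7, 0.3, seed=23)
        base = pebble_analyze(g).free_dof
        for _ in range(10):
            u, v = sorted(rng.choice(7, size=2, replace=False).tolist())
            bigger = BodyBarGraph(n_bodies=7,
                                  edges=g.edges + [(u, v, 1, "extra")])
            assert pebble_analyze(bigger).free_dof <= base

    def test_undercounted_graph_never_fully_rigid(self):
        """A connected graph with fewer than 6n-6 bars cannot be rigid."""
        rng = np.random.default_rng(29)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            edges = [(i, i + 1, int(rng.integers(1, 6))) for i in range(n - 1)]
            for _ in range(int(rng.integers(0, n))):
                u, v = sorted(rng.choice(n, size=2, replace=False).tolist())
                edges.append((u, v, int(rng.integers(1, 4))))
            g = graph_of(n, edges)
            if g.total_multiplicity >= 6 * n - 6:
                continue
            result = pebble_analyze(g)
            fully_rigid = (len(result.components) == 1 and result.free_dof == 0)
            assert not fully_rigid

    def test_components_partition_all_bodies(self):
        g = random_body_bar_graph(9, 0.5, seed=77)
        result = pebble_analyze(g)
        all_bodies = sorted(b for c in result.components for b in c)
        assert all_bodies == list(range(9))


class TestLargestRigidBody:
    def test_atom_union_of_overlapping_bodies(self, toy_interactions):
        from critres.mechanical_model import build_model

        _, s, interactions = toy_interactions
        model = build_model(s, interactions)
        result = pebble_analyze(model.graph, model=model)
        biggest = max(result.components, key=len)
        assert result.lrb_atoms == len(model.atom_union(biggest))
        assert result.lrb_atoms <= s.n_atoms

    def test_body_count_without_model(self):
        result = pebble_analyze(graph_of(2, [(0, 1, 6)]))
        assert largest_rigid_body(result) == 2

    def test_all_singletons(self):
        result = pebble_analyze(graph_of(3, []))
        assert largest_rigid_body(result) == 1
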