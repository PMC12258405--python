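"""MCTS / MO-MCTS behaviour, Pareto machinery and route extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroprompt.benchmark import generate_fixture
from retroprompt.chem import ConstraintSet, MappedMolecule, parse_target
from retroprompt.expand import Stock
from retroprompt.search import (
    SearchConfig,
    extract_routes,
    mcts_search,
    mo_mcts_search,
    pareto_fronts,
)

FAST = SearchConfig(iteration_limit=100, time_limit=5.0, seed=0)


def oracle_ranks(points):
    """Independent Pareto-rank oracle: rank = 1 + max rank of dominators."""

    def dominates(p, q):
        return all(a >= b for a, b in zip(p, q)) and any(a > b for a, b in zip(p, q))

    ranks = {}

    def rank_of(i):
        if i in ranks:
            return ranks[i]
        dominators = [j for j in range(len(points)) if j != i and dominates(points[j], points[i])]
        ranks[i] = 1 + max((rank_of(j) for j in dominators), default=0)
        return ranks[i]

    return [rank_of(i) for i in range(len(points))]


class TestParetoFronts:
    def test_worked_example(self):
        points = [(0.9, 0.2), (0.6, 0.5), (0.5, 0.4), (0.4, 0.9)]
        fronts = pareto_fronts(points)
        assert [sorted(f.indices) for f in fronts] == [[0, 1, 3], [2]]
        assert [f.rank for f in fronts] == [1, 2]

    def test_single_point(self):
        fronts = pareto_fronts([(0.3, 0.7)])
        assert len(fronts) == 1 and fronts[0].rank == 1

    def test_identical_points_share_rank_one(self):
        fronts = pareto_fronts([(0.5, 0.5)] * 4)
        assert len(fronts) == 1
        assert sorted(fronts[0].indices) == [0, 1, 2, 3]

    def test_empty_input(self):
        assert pareto_fronts([]) == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_dominance_oracle_3d(self, points):
        fronts = pareto_fronts(points)
        got = {}
        for front in fronts:
            for i in front.indices:
                got[i] = front.rank
        expected = oracle_ranks(points)
        assert [got[i] for i in range(len(points))] == expected

    def test_matches_oracle_on_random_2d(self):
        rng = np.random.default_rng(123)
        points = [tuple(p) for p in rng.random((300, 2))]
        fronts = pareto_fronts(points)
        got = {i: f.rank for f in fronts for i in f.indices}
        assert [got[i] for i in range(len(points))] == oracle_ranks(points)


class TestMctsSearch:
    def test_target_in_stock_solved_with_zero_reactions(self, library):
        mol = MappedMolecule("CC(=O)O")
        tree = mcts_search(mol, ConstraintSet(), library, Stock(["CC(=O)O"]), FAST)
        assert tree.is_solved
        (record,) = extract_routes(tree, "standard", n=5)
        assert record.tree.n_reactions == 0 and record.tree.is_solved

    def test_depth_one_target_solved_quickly(self, amide_target, amide_stock, library):
        """Oracle: depth-1 enumeration shows one template application solves it."""
        mol, cons = amide_target
        from retroprompt.expand import template_policy

        solving = [
            s
            for s in template_policy(mol, library)
            if all(r in amide_stock for r in s.reactants)
        ]
        assert solving  # the fixture is solvable in one step by construction
        config = SearchConfig(iteration_limit=10, time_limit=5.0, seed=0)
        tree = mcts_search(mol, cons, library, amide_stock, config)
        assert tree.is_solved
        best = extract_routes(tree, "standard", n=1)[0]
        assert best.tree.is_solved and best.tree.n_reactions == 1

    def test_frozen_only_disconnection_leaves_unsolved(self, amide_target, amide_stock, library):
        mol, _ = amide_target
        cons = ConstraintSet(bonds_to_freeze=frozenset({(1, 3)}))
        tree = mcts_search(mol, cons, library, amide_stock, FAST)
        assert not tree.is_solved
        records = extract_routes(tree, "standard", n=5)
        assert all(not r.tree.is_solved for r in records)

    def test_unexpandable_root_yields_root_only_tree(self, library):
        mol = MappedMolecule("C1CC1")  # cyclopropane: no template matches
        tree = mcts_search(mol, ConstraintSet(), library, Stock(["CC(=O)O"]), FAST)
        assert not tree.is_solved
        assert tree.root.children == []

    def test_iteration_budget_monotone_best_state(self, small_fixture):
        """With a fixed seed, more iterations never lose the best found route."""
        library, stock, targets = small_fixture
        bench = targets[0]
        best = []
        for iters in (10, 40):
            cfg = SearchConfig(iteration_limit=iters, time_limit=5.0, seed=0)
            tree = mcts_search(bench.target, bench.constraints, library, stock, cfg)
            records = extract_routes(tree, "standard", n=1)
            best.append(records[0].scores["state"] if records else 0.0)
        assert best[1] >= best[0]


class TestMoMctsSearch:
    def test_single_objective_reduction_matches_mcts(self, small_fixture):
        library, stock, targets = small_fixture
        bench = targets[1]
        cfg = SearchConfig(
            iteration_limit=50, time_limit=5.0, seed=0, objectives=("state",)
        )
        a = mcts_search(bench.target, bench.constraints, library, stock, cfg)
        from retroprompt.search import _run_search

        b = _run_search(bench.target, bench.constraints, library, stock, cfg)
        keys_a = sorted(r.tree.canonical_key() for r in extract_routes(a, "standard", 50))
        keys_b = sorted(r.tree.canonical_key() for r in extract_routes(b, "standard", 50))
        assert keys_a == keys_b

    def test_seeded_reproducibility(self, small_fixture):
        library, stock, targets = small_fixture
        bench = targets[2]
        keys = []
        for _ in range(2):
            cfg = SearchConfig(iteration_limit=60, time_limit=5.0, seed=7,
                               objectives=("state", "broken-bonds"))
            tree = mo_mcts_search(bench.target, bench.constraints, library, stock, cfg)
            keys.append([r.tree.canonical_key() for r in extract_routes(tree, "mo_front", 10)])
        assert keys[0] == keys[1]

    def test_extracted_front_is_mutually_non_dominated(self, small_fixture):
        library, stock, targets = small_fixture
        bench = targets[3]
        tree = mo_mcts_search(
            bench.target,
            bench.constraints,
            library,
            stock,
            SearchConfig(iteration_limit=80, time_limit=5.0, seed=1,
                         objectives=("state", "broken-bonds")),
        )
        records = extract_routes(tree, "mo_front", n=50)
        front = [
            (r.scores["state"], r.scores["broken-bonds"])
            for r in records
            if r.metadata.get("pareto_rank") == 1
        ]
        assert front
        for i, p in enumerate(front):
            for j, q in enumerate(front):
                if i != j:
                    assert not (
                        all(a >= b for a, b in zip(p, q))
                        and any(a > b for a, b in zip(p, q))
                    )

    def test_requires_break_bonds(self, library):
        mol = MappedMolecule("CC(=O)NC")
        with pytest.raises(ValueError):
            mo_mcts_search(mol, ConstraintSet(), library, Stock(["CC(=O)O"]),
                           SearchConfig(objectives=("state", "broken-bonds")))


class TestHardConstraintConservation:
    def test_no_extracted_route_breaks_a_frozen_bond(self):
        library, stock, targets = generate_fixture(
            6, (2, 3), seed=3, n_break=2, n_freeze=1
        )
        for bench in targets:
            assert bench.constraints.bonds_to_freeze
            for strategy, extraction in (
                ("standard", "standard"),
                ("mo-search", "mo_front"),
            ):
                search = mcts_search if strategy == "standard" else mo_mcts_search
                cfg = SearchConfig(
                    iteration_limit=60,
                    time_limit=5.0,
                    seed=0,
                    objectives=("state",) if strategy == "standard" else ("state", "broken-bonds"),
                )
                tree = search(bench.target, bench.constraints, library, stock, cfg)
                for record in extract_routes(tree, extraction, n=20):
                    assert not (
                        record.tree.all_broken_bonds()
                        & bench.constraints.bonds_to_freeze
                    )

    def test_routes_respect_max_depth(self, small_fixture):
        library, stock, targets = small_fixture
        bench = targets[4]
        cfg = SearchConfig(iteration_limit=60, time_limit=5.0, seed=0, max_depth=3)
        tree = mcts_search(bench.target, bench.constraints, library, stock, cfg)
        for record in extract_routes(tree, "standard", n=20):
            assert record.tree.max_reaction_depth < 3
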