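"""Reaction tree serialization, constraint checks, similarity and diversity."""

import json

import pytest

from retroprompt.benchmark import _chain_route, illustration_routes
from retroprompt.chem import ConstraintSet, bond_key
from retroprompt.routes import (
    ReactionTree,
    RouteComparisonError,
    dissimilarity_to_reference,
    diversity,
    route_similarity,
    satisfies_constraints,
)

CHAIN = list(range(1, 9))


def one_step(bond, left, right):
    return _chain_route((CHAIN, bond, (left,), (right,)))


class TestSerialization:
    def test_round_trip_equality(self, small_fixture):
        _, _, targets = small_fixture
        for bench in targets[:5]:
            tree = bench.reference_route
            clone = ReactionTree.from_json(tree.to_json())
            assert clone == tree
            assert clone.to_dict() == tree.to_dict()

    def test_hand_written_depth_one_route(self):
        data = {
            "type": "mol",
            "smiles": "[CH3:10][C:1](=[O:2])[NH:3][CH3:11]",
            "in_stock": False,
            "children": [
                {
                    "type": "reaction",
                    "template_name": "retro_amide",
                    "source_policy": "template",
                    "broken_bonds": [[1, 3]],
                    "children": [
                        {"type": "mol", "smiles": "O[C:1](=[O:2])[CH3:10]", "in_stock": True},
                        {"type": "mol", "smiles": "[NH2:3][CH3:11]", "in_stock": True},
                    ],
                }
            ],
        }
        tree = ReactionTree.from_dict(data)
        assert tree.n_reactions == 1
        assert tree.is_solved
        assert tree.all_broken_bonds() == {(1, 3)}
        assert len(tree.leaves()) == 2

    def test_unknown_extra_keys_preserved(self):
        data = {
            "type": "mol",
            "smiles": "CC(=O)O",
            "in_stock": True,
            "vendor": "acme",
            "children": [],
        }
        round_tripped = ReactionTree.from_dict(data).to_dict()
        assert round_tripped["vendor"] == "acme"

    def test_schema_error_reports_path(self):
        bad = {"type": "mol", "smiles": "CC", "children": [{"type": "mol", "smiles": "C",
                                                            "children": []}]}
        with pytest.raises(ValueError, match=r"\$/children/0"):
            ReactionTree.from_dict(bad)


class TestSatisfiesConstraints:
    def test_empty_constraints_always_satisfied(self):
        route = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        assert satisfies_constraints(route, ConstraintSet())

    def test_partial_break_coverage_fails(self):
        route = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        cons = ConstraintSet(frozenset({bond_key(4, 5), bond_key(6, 7)}))
        assert not satisfies_constraints(route, cons)

    def test_breaking_a_frozen_bond_fails_even_if_breaks_covered(self):
        routes, _, _ = illustration_routes()
        route = routes[2]  # breaks (4,5), (2,3), (6,7), plus peel bonds
        cons = ConstraintSet(
            bonds_to_break=frozenset({bond_key(4, 5)}),
            bonds_to_freeze=frozenset({bond_key(1, 2)}),  # broken by the peel
        )
        assert not satisfies_constraints(route, cons)

    def test_union_monotonicity(self):
        route = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        c1 = ConstraintSet(frozenset({bond_key(4, 5)}))
        c2 = ConstraintSet(frozenset(), frozenset({bond_key(1, 2)}))
        if satisfies_constraints(route, c1.union(c2)):
            assert satisfies_constraints(route, c1)


class TestRouteSimilarity:
    def test_identical_single_step_routes_bond_component_is_one(self):
        a = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        b = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        # bond sets identical; atom component 4/6 under molecule-count normalisation
        assert route_similarity(a, b) == pytest.approx(0.5 * 1.0 + 0.5 * (4 / 6))

    def test_disjoint_disconnections_zero_bond_component(self):
        a = one_step((2, 3), [1, 2], [3, 4, 5, 6, 7, 8])
        b = one_step((6, 7), [1, 2, 3, 4, 5, 6], [7, 8])
        sim = route_similarity(a, b)
        # bond component 0; atom overlap only via partial group Jaccards
        assert sim < 0.5

    def test_symmetry_and_bounds(self):
        routes, _, _ = illustration_routes()
        for a in routes:
            for b in routes:
                s1, s2 = route_similarity(a, b), route_similarity(b, a)
                assert s1 == pytest.approx(s2)
                assert 0.0 <= s1 <= 1.0

    def test_self_similarity_quirk_below_one(self):
        """Molecule-count normalisation makes multi-step self-similarity < 1."""
        routes, _, _ = illustration_routes()
        for route in routes:
            assert route_similarity(route, route) < 1.0

    def test_different_targets_incomparable(self):
        a = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        b = _chain_route(([1, 2, 3], (1, 2), ([1],), ([2, 3],)))
        with pytest.raises(RouteComparisonError):
            route_similarity(a, b)


class TestGammaKappa:
    def _three_routes(self):
        r1 = one_step((2, 3), [1, 2], [3, 4, 5, 6, 7, 8])
        r2 = one_step((4, 5), [1, 2, 3, 4], [5, 6, 7, 8])
        r3 = one_step((6, 7), [1, 2, 3, 4, 5, 6], [7, 8])
        return [r1, r2, r3]

    def test_gamma_matches_hand_computation(self):
        routes = self._three_routes()
        reference = routes[:2]
        table = [[route_similarity(r, ref) for ref in reference] for r in routes]
        zeta_max = sum(max(row) for row in table) / len(routes)
        assert dissimilarity_to_reference(routes, reference) == pytest.approx(
            1.0 - zeta_max
        )

    def test_gamma_self_reference_nonzero_by_quirk(self):
        route = self._three_routes()[0]
        gamma = dissimilarity_to_reference([route], [route])
        assert 0.0 < gamma < 0.5  # slight non-zero, not forced to 0

    def test_kappa_matches_hand_computation(self):
        routes = self._three_routes()
        mins = []
        for i, r in enumerate(routes):
            mins.append(
                min(route_similarity(r, o) for j, o in enumerate(routes) if j != i)
            )
        expected = 1.0 - sum(mins) / len(routes)
        assert diversity(routes) == pytest.approx(expected)

    def test_adding_routes_never_raises_a_route_min_similarity(self):
        """min-similarity is monotone per route as the set grows.

        (kappa itself averages the minima, so a duplicate adds a new low term
        and the average can shift; the monotone quantity is each route's own
        minimum.)
        """
        routes = self._three_routes()

        def min_sim(i, pool):
            return min(
                route_similarity(pool[i], o)
                for j, o in enumerate(pool)
                if j != i
            )

        extended = routes + [routes[0]]
        for i in range(len(routes)):
            assert min_sim(i, extended) <= min_sim(i, routes) + 1e-12

    def test_order_invariance(self):
        routes = self._three_routes()
        assert diversity(routes) == pytest.approx(diversity(routes[::-1]))
        assert dissimilarity_to_reference(routes, routes[:2]) == pytest.approx(
            dissimilarity_to_reference(routes[::-1], routes[:2][::-1])
        )

    def test_degenerate_inputs_raise(self):
        routes = self._three_routes()
        with pytest.raises(ValueError):
            diversity(routes[:1])
        with pytest.raises(ValueError):
            dissimilarity_to_reference(routes, [])
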