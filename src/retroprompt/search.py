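"""Monte-Carlo tree search over retro steps, single- and multi-objective.

The search state at a node is the multiset of frontier molecules (with their
per-branch reaction depths) still to be made.  Expanding a node applies one
retro prediction to one frontier molecule; predictions come from the
configured expansion policies and pass through the frozen-bonds filter, so no
state reachable by the search ever violates a bonds-to-freeze constraint.

Rewards are immediate evaluations of the reached state (no rollout phase):
the state score alone for the single-objective search, or a vector of
(state score, broken bonds score) for the multi-objective search.  Value
accumulators store running sums per objective; selection uses per-objective
mean-plus-UCB vectors, and the multi-objective rule picks uniformly at random
(seeded) among the Pareto-non-dominated children.

Route extraction gathers solved states and search-tree leaves, deduplicates
identical reaction trees and ranks them by the requested strategy; the
multi-objective strategy returns the primary Pareto front of
(state, broken bonds), padded from lower ranks up to the requested count.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

from .chem import ConstraintSet, MappedMolecule
from .expand import RetroStep, Stock, frozen_filter, multi_expand
from .routes import MoleculeNode, ReactionNode, ReactionTree, RouteRecord
from .scoring import broken_bonds_score, combined_score, state_score

__all__ = [
    "SearchConfig",
    "SearchNode",
    "SearchTree",
    "ParetoFront",
    "pareto_fronts",
    "mcts_search",
    "mo_mcts_search",
    "extract_routes",
]


@dataclass(frozen=True)
class SearchConfig:
    """Hyper-parameters of one search run."""

    max_depth: int = 6
    iteration_limit: int = 100
    time_limit: float = 300.0
    ucb_constant: float = 1.4
    seed: int = 0
    expansion_k: int = 50
    beam: int = 5
    objectives: tuple[str, ...] = ("state",)
    expansion_mode: Literal["standard", "disconnection_aware"] = "standard"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.time_limit <= 0:
            raise ValueError("time_limit must be > 0")
        if not self.objectives:
            raise ValueError("at least one objective is required")


@dataclass(frozen=True)
class _Entry:
    """One frontier molecule: unique id, molecule, branch depth, stock flag."""

    uid: int
    mol: MappedMolecule
    depth: int
    in_stock: bool


class SearchNode:
    """One state of the search tree."""

    __slots__ = (
        "entries",
        "parent",
        "step",
        "replaced_uid",
        "children",
        "untried",
        "visits",
        "value_sum",
        "reward",
    )

    def __init__(
        self,
        entries: tuple[_Entry, ...],
        parent: Optional["SearchNode"] = None,
        step: Optional[RetroStep] = None,
        replaced_uid: Optional[int] = None,
        n_objectives: int = 1,
    ):
        self.entries = entries
        self.parent = parent
        self.step = step
        self.replaced_uid = replaced_uid
        self.children: list[SearchNode] = []
        self.untried: Optional[list[tuple[int, RetroStep]]] = None
        self.visits = 0
        self.value_sum = np.zeros(n_objectives)
        self.reward: Optional[np.ndarray] = None

    @property
    def is_solved(self) -> bool:
        return all(e.in_stock for e in self.entries)

    @property
    def mean_value(self) -> np.ndarray:
        return self.value_sum / max(self.visits, 1)

    def depth_of(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d


@dataclass
class ParetoFront:
    """One rank of the iterated non-dominated sort (maximisation)."""

    rank: int
    indices: list[int]
    members: list[tuple[float, ...]]


def _dominates(p: Sequence[float], q: Sequence[float]) -> bool:
    return all(a >= b for a, b in zip(p, q)) and any(a > b for a, b in zip(p, q))


def pareto_fronts(points: Sequence[Sequence[float]]) -> list[ParetoFront]:
    """Partition points into Pareto ranks by iterated non-dominated sorting.

    Maximisation on every axis; ties (equal vectors) share a rank; order
    within a rank follows the input order.
    """
    remaining = list(range(len(points)))
    fronts: list[ParetoFront] = []
    rank = 1
    while remaining:
        front = [
            i
            for i in remaining
            if not any(_dominates(points[j], points[i]) for j in remaining if j != i)
        ]
        fronts.append(
            ParetoFront(rank=rank, indices=front, members=[tuple(points[i]) for i in front])
        )
        chosen = set(front)
        remaining = [i for i in remaining if i not in chosen]
        rank += 1
    return fronts


class SearchTree:
    """The result of a search: root node plus run context for extraction."""

    def __init__(
        self,
        root: SearchNode,
        target: MappedMolecule,
        constraints: ConstraintSet,
        stock: Stock,
        config: SearchConfig,
        iterations_run: int = 0,
        search_time: float = 0.0,
    ):
        self.root = root
        self.target = target
        self.constraints = constraints
        self.stock = stock
        self.config = config
        self.iterations_run = iterations_run
        self.search_time = search_time

    def nodes(self) -> Iterator[SearchNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    @property
    def is_solved(self) -> bool:
        return any(node.is_solved for node in self.nodes())

    def route_for(self, node: SearchNode) -> ReactionTree:
        return _build_route(self.root, node)


def _build_route(root: SearchNode, node: SearchNode) -> ReactionTree:
    """Reconstruct the reaction tree along the path root -> node."""
    steps: dict[int, tuple[RetroStep, tuple[_Entry, ...]]] = {}
    current = node
    while current.parent is not None:
        new_entries = tuple(
            e for e in current.entries if all(e.uid != p.uid for p in current.parent.entries)
        )
        steps[current.replaced_uid] = (current.step, new_entries)
        current = current.parent
    root_entry = root.entries[0]

    stock_flags = {e.uid: e.in_stock for n in _path_nodes(node) for e in n.entries}

    def build(entry: _Entry) -> MoleculeNode:
        mol_node = MoleculeNode(mol=entry.mol, in_stock=stock_flags.get(entry.uid, entry.in_stock))
        if entry.uid in steps:
            step, children = steps[entry.uid]
            mol_node.reaction = ReactionNode(
                template_name=step.template_name,
                source_policy=step.source_policy,
                broken=step.broken,
                children=[build(c) for c in children],
                extra={"prior": step.prior},
            )
        return mol_node

    return ReactionTree(build(root_entry))


def _path_nodes(node: SearchNode) -> Iterator[SearchNode]:
    while node is not None:
        yield node
        node = node.parent


class _Expander:
    """Cached, filtered expansion of a molecule under the run constraints."""

    def __init__(self, library, constraints: ConstraintSet, config: SearchConfig):
        self.library = library
        self.constraints = constraints
        self.config = config
        self._cache: dict[str, list[RetroStep]] = {}

    def __call__(self, mol: MappedMolecule) -> list[RetroStep]:
        if mol.smiles not in self._cache:
            steps = multi_expand(
                mol,
                self.constraints,
                self.library,
                k=self.config.expansion_k,
                beam=self.config.beam,
                mode=self.config.expansion_mode,
            )
            self._cache[mol.smiles] = frozen_filter(steps, self.constraints.bonds_to_freeze)
        return self._cache[mol.smiles]


def _evaluate(tree: SearchTree, node: SearchNode) -> np.ndarray:
    route = tree.route_for(node)
    values = []
    for objective in tree.config.objectives:
        if objective == "state":
            values.append(state_score(route))
        elif objective == "broken-bonds":
            values.append(
                broken_bonds_score(
                    route, tree.constraints.bonds_to_break, tree.config.max_depth
                )
            )
        else:
            raise ValueError(f"unknown objective {objective!r}")
    return np.asarray(values, dtype=float)


def _generate_actions(
    node: SearchNode, expander: _Expander, config: SearchConfig
) -> list[tuple[int, RetroStep]]:
    actions: list[tuple[int, RetroStep]] = []
    for entry in node.entries:
        if entry.in_stock or entry.depth >= config.max_depth:
            continue
        for step in expander(entry.mol):
            actions.append((entry.uid, step))
    return actions


def _select_child(node: SearchNode, config: SearchConfig, rng: np.random.Generator) -> SearchNode:
    log_n = math.log(max(node.visits, 1))
    ucb = []
    for child in node.children:
        bonus = config.ucb_constant * math.sqrt(log_n / child.visits)
        ucb.append(child.mean_value + bonus)
    if len(config.objectives) == 1:
        best = max(range(len(ucb)), key=lambda i: ucb[i][0])
        return node.children[best]
    vectors = [tuple(v) for v in ucb]
    front = [
        i
        for i in range(len(vectors))
        if not any(_dominates(vectors[j], vectors[i]) for j in range(len(vectors)) if j != i)
    ]
    return node.children[front[int(rng.integers(len(front)))]]


def _run_search(
    target: MappedMolecule,
    constraints: ConstraintSet,
    library,
    stock: Stock,
    config: SearchConfig,
) -> SearchTree:
    if "broken-bonds" in config.objectives and not constraints.bonds_to_break:
        raise ValueError(
            "the broken-bonds objective needs a non-empty set of bonds to break"
        )
    constraints.validate_against(target)
    rng = np.random.default_rng(config.seed)
    n_obj = len(config.objectives)
    uid_counter = [0]

    def next_uid() -> int:
        uid_counter[0] += 1
        return uid_counter[0]

    root = SearchNode(
        entries=(_Entry(0, target, 0, target in stock),),
        n_objectives=n_obj,
    )
    tree = SearchTree(root, target, constraints, stock, config)
    expander = _Expander(library, constraints, config)

    start = time.monotonic()
    iterations = 0
    for _ in range(config.iteration_limit):
        if time.monotonic() - start > config.time_limit:
            break
        iterations += 1
        node = root
        # selection: descend through fully expanded nodes
        while True:
            if node.untried is None:
                node.untried = _generate_actions(node, expander, config)
            if node.untried or not node.children:
                break
            node = _select_child(node, config, rng)
        # expansion
        if node.untried:
            uid, step = node.untried.pop(0)
            replaced = next(e for e in node.entries if e.uid == uid)
            new_entries = tuple(
                _Entry(next_uid(), r, replaced.depth + 1, r in stock) for r in step.reactants
            )
            child = SearchNode(
                entries=tuple(e for e in node.entries if e.uid != uid) + new_entries,
                parent=node,
                step=step,
                replaced_uid=uid,
                n_objectives=n_obj,
            )
            node.children.append(child)
            node = child
        # evaluation + backpropagation
        if node.reward is None:
            node.reward = _evaluate(tree, node)
        reward = node.reward
        walker: Optional[SearchNode] = node
        while walker is not None:
            walker.visits += 1
            walker.value_sum += reward
            walker = walker.parent

    tree.iterations_run = iterations
    tree.search_time = time.monotonic() - start
    return tree


def mcts_search(
    target: MappedMolecule,
    constraints: ConstraintSet,
    library,
    stock: Stock,
    config: SearchConfig = SearchConfig(),
) -> SearchTree:
    """Single-objective MCTS guided by the state score."""
    if len(config.objectives) != 1:
        config = replace(config, objectives=("state",))
    return _run_search(target, constraints, library, stock, config)


def mo_mcts_search(
    target: MappedMolecule,
    constraints: ConstraintSet,
    library,
    stock: Stock,
    config: SearchConfig = SearchConfig(objectives=("state", "broken-bonds")),
) -> SearchTree:
    """Multi-objective MCTS with vector rewards and Pareto-based selection."""
    if len(config.objectives) < 2:
        config = replace(config, objectives=("state", "broken-bonds"))
    return _run_search(target, constraints, library, stock, config)


def extract_routes(
    tree: SearchTree,
    strategy: Literal["standard", "route_ranking", "mo_front"] = "standard",
    n: int = 10,
) -> list[RouteRecord]:
    """Extract, score, deduplicate and rank routes from a finished search."""
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates: list[SearchNode] = [
        node for node in tree.nodes() if node.is_solved or not node.children
    ]
    records: dict[str, RouteRecord] = {}
    for node in candidates:
        route = tree.route_for(node)
        key = route.canonical_key()
        if key in records:
            continue
        scores = {"state": state_score(route)}
        if tree.constraints.bonds_to_break:
            scores["broken-bonds"] = broken_bonds_score(
                route, tree.constraints.bonds_to_break, tree.config.max_depth
            )
            scores["combined"] = combined_score(scores["state"], scores["broken-bonds"])
        records[key] = RouteRecord(
            tree=route,
            scores=scores,
            metadata={"solved": route.is_solved, "node_visits": node.visits},
        )
    ordered = sorted(
        records.values(), key=lambda r: (-r.scores["state"], r.tree.canonical_key())
    )
    if strategy == "standard":
        return ordered[:n]
    if strategy == "route_ranking":
        if any("combined" not in r.scores for r in ordered):
            raise ValueError("route_ranking needs bonds to break to be prompted")
        return sorted(
            ordered, key=lambda r: (-r.scores["combined"], r.tree.canonical_key())
        )[:n]
    if strategy == "mo_front":
        if any("broken-bonds" not in r.scores for r in ordered):
            raise ValueError("mo_front needs bonds to break to be prompted")
        points = [(r.scores["state"], r.scores["broken-bonds"]) for r in ordered]
        out: list[RouteRecord] = []
        for front in pareto_fronts(points):
            for i in front.indices:
                ordered[i].metadata["pareto_rank"] = front.rank
            if front.rank == 1:
                out.extend(ordered[i] for i in front.indices)
            elif len(out) < n:
                out.extend(ordered[i] for i in front.indices[: n - len(out)])
        return out[: max(n, len([r for r in out if r.metadata.get("pareto_rank") == 1]))]
    raise ValueError(f"unknown extraction strategy {strategy!r}")
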