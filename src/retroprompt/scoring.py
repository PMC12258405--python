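"""Route objectives: state score, broken bonds score, combined ranking.

State score
    ``0.95 * f + 0.05 * g(L)`` where ``f`` is the fraction of leaf molecules
    in stock and ``g`` is a decreasing logistic squash of the number of
    reactions ``L``, normalised so ``g(0) = 1``.  It rewards short routes
    whose precursors are purchasable and is the single objective of the
    standard search.

Broken bonds score
    Given the prompted bonds to break ``B`` and a route, every bond broken by
    a reaction at depth ``d`` earns credit ``(D_max - d) / D_max`` (the first
    reaction has depth 0), so disconnections early in the tree are worth
    more.  Any bonds left unbroken contribute one joint penalty term worth
    the credit of breaking at the maximum depth ``D_max`` — which is zero.
    The sum is normalised by the number of productive components: ``|B|``
    when every prompted bond is broken, or ``n_broken + 1`` (the broken-bond
    terms plus the joint unbroken term) otherwise.  The score is 1 exactly
    when all prompted bonds break in the first reaction and 0 exactly when
    none break anywhere.

Combined score
    The equal-weight linear combination ``0.5 * state + 0.5 * broken_bonds``
    used by the route-ranking strategy at extraction time.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Sequence

from .chem import BondKey
from .routes import ReactionTree, RouteRecord

__all__ = [
    "state_score",
    "broken_bonds_score",
    "combined_score",
    "score_route",
    "rank_routes",
    "DEFAULT_MAX_DEPTH",
]

DEFAULT_MAX_DEPTH = 6

_W_STOCK = 0.95
_W_LENGTH = 0.05
_SQUASH_MID = 4.0  # route length at which the length reward halves (pre-normalisation)


def _length_squash(n_reactions: int) -> float:
    # logistic squash, rescaled so a zero-length route scores exactly 1
    raw = 1.0 / (1.0 + math.exp(n_reactions - _SQUASH_MID))
    norm = 1.0 / (1.0 + math.exp(-_SQUASH_MID))
    return raw / norm


def state_score(route: ReactionTree, stock=None) -> float:
    """Solvability/length objective in [0, 1].

    Uses the in-stock flags on the route's leaves; pass ``stock`` to refresh
    the flags first.
    """
    if stock is not None:
        route.update_stock_flags(stock)
    leaves = route.leaves()
    fraction = sum(leaf.in_stock for leaf in leaves) / len(leaves)
    return _W_STOCK * fraction + _W_LENGTH * _length_squash(route.n_reactions)


def broken_bonds_score(
    route: ReactionTree,
    break_set: Iterable[BondKey],
    d_max: int = DEFAULT_MAX_DEPTH,
) -> float:
    """Depth-weighted credit for disconnecting the prompted bonds early."""
    break_set = frozenset(break_set)
    if not break_set:
        raise ValueError(
            "broken bonds score is undefined for an empty set of bonds to break"
        )
    if d_max < 1:
        raise ValueError("d_max must be >= 1")

    first_break: dict[BondKey, int] = {}
    for reaction, depth in route.reactions():
        for bond in reaction.broken & break_set:
            if bond not in first_break or depth < first_break[bond]:
                first_break[bond] = depth

    n_broken = len(first_break)
    credit = sum(max(d_max - d, 0) / d_max for d in first_break.values())
    if n_broken == len(break_set):
        n_components = len(break_set)
    else:
        # unbroken remainder: one joint term, worth breaking at D_max (zero)
        n_components = n_broken + 1
    return credit / n_components


def combined_score(state: float, broken: float) -> float:
    return 0.5 * state + 0.5 * broken


def score_route(
    route: ReactionTree,
    break_set: Iterable[BondKey] = (),
    d_max: int = DEFAULT_MAX_DEPTH,
    stock=None,
) -> dict:
    """Compute the full score mapping for one route."""
    scores = {"state": state_score(route, stock)}
    break_set = frozenset(break_set)
    if break_set:
        scores["broken-bonds"] = broken_bonds_score(route, break_set, d_max)
        scores["combined"] = combined_score(scores["state"], scores["broken-bonds"])
    return scores


def rank_routes(
    records: Sequence[RouteRecord],
    strategy: Literal["standard", "route_ranking", "mo"] = "standard",
) -> list[RouteRecord]:
    """Order routes by the strategy's ranking score.

    ``standard`` sorts by state score, ``route_ranking`` by the combined
    score, ``mo`` by Pareto rank of (state, broken bonds) and then state
    score within a rank.  Ties break on the route's canonical serialization.
    """
    if strategy in ("standard", "route_ranking"):
        key_name = "state" if strategy == "standard" else "combined"
        return sorted(
            records,
            key=lambda r: (-r.scores[key_name], r.tree.canonical_key()),
        )
    if strategy == "mo":
        from .search import pareto_fronts  # local import to avoid a cycle

        points = [(r.scores["state"], r.scores["broken-bonds"]) for r in records]
        ordered: list[RouteRecord] = []
        for front in pareto_fronts(points):
            members = [records[i] for i in front.indices]
            members.sort(key=lambda r: (-r.scores["state"], r.tree.canonical_key()))
            ordered.extend(members)
        return ordered
    raise ValueError(f"unknown ranking strategy {strategy!r}")
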