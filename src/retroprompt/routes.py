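"""Reaction trees (synthesis routes), serialization and route metrics.

A route is a bipartite tree alternating molecule and reaction nodes, rooted at
the target molecule.  Leaves are the starting materials; a route is *solved*
when every leaf is in stock.  The depth of a reaction is its number of
reaction ancestors, so the reaction applied directly to the target has
depth 0.

Route similarity follows a disconnection/atom-grouping contract: two routes to
the same target are compared through (a) the Jaccard overlap of the
target-atom pairs they disconnect and (b) the agreement of the partitions of
target atoms induced by their leaf molecules, normalised by the total molecule
count of both routes.  Because of that normalisation the self-similarity of a
multi-molecule route is below one — an intentional, documented quirk of the
metric family this approximates.  Dissimilarity to a reference set is
``gamma = 1 - zeta_max`` (zeta_max: average maximum similarity of each route
to the reference routes) and within-set diversity is ``kappa = 1 - zeta_min``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .chem import BondKey, ConstraintSet, MappedMolecule, bond_key

__all__ = [
    "MoleculeNode",
    "ReactionNode",
    "ReactionTree",
    "RouteRecord",
    "RouteComparisonError",
    "satisfies_constraints",
    "route_similarity",
    "dissimilarity_to_reference",
    "diversity",
]


class RouteComparisonError(ValueError):
    """Raised when routes with different targets are compared."""


@dataclass
class MoleculeNode:
    mol: MappedMolecule
    in_stock: bool = False
    reaction: Optional["ReactionNode"] = None  # None for leaves
    extra: dict = field(default_factory=dict)


@dataclass
class ReactionNode:
    template_name: str
    source_policy: str
    broken: frozenset[BondKey]
    children: list[MoleculeNode] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


class ReactionTree:
    """Alternating molecule/reaction tree rooted at the target molecule."""

    def __init__(self, root: MoleculeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def molecules(self) -> Iterator[MoleculeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.reaction is not None:
                stack.extend(reversed(node.reaction.children))

    def reactions(self) -> Iterator[tuple[ReactionNode, int]]:
        """Yield (reaction, depth) pairs; depth counts reaction ancestors."""
        stack: list[tuple[MoleculeNode, int]] = [(self.root, 0)]
        while stack:
            node, depth = stack.pop()
            if node.reaction is not None:
                yield node.reaction, depth
                for child in reversed(node.reaction.children):
                    stack.append((child, depth + 1))

    def leaves(self) -> list[MoleculeNode]:
        return [m for m in self.molecules() if m.reaction is None]

    @property
    def n_reactions(self) -> int:
        return sum(1 for _ in self.reactions())

    @property
    def max_reaction_depth(self) -> int:
        return max((d for _, d in self.reactions()), default=-1)

    @property
    def is_solved(self) -> bool:
        return all(leaf.in_stock for leaf in self.leaves())

    def all_broken_bonds(self) -> frozenset[BondKey]:
        out: set[BondKey] = set()
        for rxn, _ in self.reactions():
            out |= rxn.broken
        return frozenset(out)

    def update_stock_flags(self, stock) -> None:
        for node in self.molecules():
            node.in_stock = node.mol in stock

    # -- serialization (nested mol/reaction JSON dialect) ------------------

    _MOL_KEYS = {"type", "smiles", "in_stock", "children"}
    _RXN_KEYS = {"type", "template_name", "source_policy", "broken_bonds", "children"}

    def to_dict(self) -> dict:
        def mol_dict(node: MoleculeNode) -> dict:
            out = {"type": "mol", "smiles": node.mol.smiles, "in_stock": node.in_stock}
            out.update(node.extra)
            if node.reaction is not None:
                out["children"] = [rxn_dict(node.reaction)]
            return out

        def rxn_dict(rxn: ReactionNode) -> dict:
            out = {
                "type": "reaction",
                "template_name": rxn.template_name,
                "source_policy": rxn.source_policy,
                "broken_bonds": [list(b) for b in sorted(rxn.broken)],
            }
            out.update(rxn.extra)
            out["children"] = [mol_dict(c) for c in rxn.children]
            return out

        return mol_dict(self.root)

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionTree":
        def parse_mol(data: dict, path: str) -> MoleculeNode:
            if data.get("type") != "mol":
                raise ValueError(f"{path}: expected a 'mol' node, got {data.get('type')!r}")
            if "smiles" not in data:
                raise ValueError(f"{path}: molecule node lacks 'smiles'")
            children = data.get("children", [])
            if len(children) > 1:
                raise ValueError(f"{path}: molecule node has more than one reaction child")
            node = MoleculeNode(
                mol=MappedMolecule(data["smiles"]),
                in_stock=bool(data.get("in_stock", False)),
                extra={k: v for k, v in data.items() if k not in cls._MOL_KEYS},
            )
            if children:
                node.reaction = parse_rxn(children[0], f"{path}/children/0")
            return node

        def parse_rxn(data: dict, path: str) -> ReactionNode:
            if data.get("type") != "reaction":
                raise ValueError(f"{path}: expected a 'reaction' node, got {data.get('type')!r}")
            children = data.get("children", [])
            if not children:
                raise ValueError(f"{path}: reaction node has no reactant children")
            return ReactionNode(
                template_name=str(data.get("template_name", "")),
                source_policy=str(data.get("source_policy", "template")),
                broken=frozenset(bond_key(*b) for b in data.get("broken_bonds", [])),
                children=[
                    parse_mol(c, f"{path}/children/{i}") for i, c in enumerate(children)
                ],
                extra={k: v for k, v in data.items() if k not in cls._RXN_KEYS},
            )

        return cls(parse_mol(data, "$"))

    def to_json(self, path: "str | Path | None" = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: "str | Path") -> "ReactionTree":
        if isinstance(text_or_path, Path) or (
            isinstance(text_or_path, str) and not text_or_path.lstrip().startswith("{")
        ):
            text = Path(text_or_path).read_text()
        else:
            text = str(text_or_path)
        return cls.from_dict(json.loads(text))

    def canonical_key(self) -> str:
        """Deterministic serialization used for route deduplication."""

        def mol_key(node: MoleculeNode) -> tuple:
            if node.reaction is None:
                return (node.mol.identity,)
            return (
                node.mol.identity,
                tuple(sorted(node.reaction.broken)),
                tuple(sorted(mol_key(c) for c in node.reaction.children)),
            )

        return repr(mol_key(self.root))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReactionTree) and self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())


@dataclass
class RouteRecord:
    """A route plus its scores and provenance metadata."""

    tree: ReactionTree
    scores: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def satisfies_constraints(route: ReactionTree, constraints: ConstraintSet) -> bool:
    """True iff all bonds to break are disconnected and no frozen bond is."""
    broken = route.all_broken_bonds()
    if not constraints.bonds_to_break <= broken:
        return False
    return not (broken & constraints.bonds_to_freeze)


# --- similarity ------------------------------------------------------------


def _target_groups(route: ReactionTree) -> tuple[frozenset[int], list[frozenset[int]], int]:
    """Target map set, leaf-induced target-atom groups, total molecule count."""
    target_maps = route.root.mol.map_numbers
    groups = [leaf.mol.map_numbers & target_maps for leaf in route.leaves()]
    n_mols = sum(1 for _ in route.molecules())
    return target_maps, [frozenset(g) for g in groups], n_mols


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def route_similarity(r1: ReactionTree, r2: ReactionTree) -> float:
    """Similarity in [0, 1] of two routes to the same target.

    Mean of a bond component (Jaccard of disconnected target-atom pairs) and
    an atom component (best-match agreement of the leaf-induced target-atom
    partitions, normalised by the total molecule count of both routes).
    """
    if r1.root.mol.identity != r2.root.mol.identity:
        raise RouteComparisonError(
            f"routes target different molecules: "
            f"{r1.root.mol.identity} vs {r2.root.mol.identity}"
        )
    t1, g1, n1 = _target_groups(r1)
    b1 = {b for b in r1.all_broken_bonds() if set(b) <= t1}
    t2, g2, n2 = _target_groups(r2)
    b2 = {b for b in r2.all_broken_bonds() if set(b) <= t2}

    if b1 or b2:
        bond_sim = len(b1 & b2) / len(b1 | b2)
    else:
        bond_sim = 1.0

    agreement = sum(max((_jaccard(g, h) for h in g2), default=0.0) for g in g1)
    agreement += sum(max((_jaccard(h, g) for g in g1), default=0.0) for h in g2)
    atom_sim = agreement / (n1 + n2)

    return 0.5 * bond_sim + 0.5 * atom_sim


def dissimilarity_to_reference(
    routes: Sequence[ReactionTree], reference_routes: Sequence[ReactionTree]
) -> float:
    """gamma = 1 - zeta_max: average max similarity of each route to the reference set."""
    if not routes:
        raise ValueError("no routes to compare")
    if not reference_routes:
        raise ValueError("empty reference route set")
    zeta_max = sum(
        max(route_similarity(r, ref) for ref in reference_routes) for r in routes
    ) / len(routes)
    return 1.0 - zeta_max


def diversity(routes: Sequence[ReactionTree]) -> float:
    """kappa = 1 - zeta_min: average minimum similarity within the route set."""
    if len(routes) < 2:
        raise ValueError("diversity needs at least two routes")
    zeta_min = sum(
        min(route_similarity(r, other) for j, other in enumerate(routes) if j != i)
        for i, r in enumerate(routes)
    ) / len(routes)
    return 1.0 - zeta_min
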