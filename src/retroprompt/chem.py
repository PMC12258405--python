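"""Atom-mapped molecules, bond identities and bond constraints.

Bond constraints ("bonds to break", "bonds to freeze") are anchored to atom-map
numbers on the target molecule.  A map number is a positive integer attached to
an atom in SMILES (``[N:1]``) that survives canonicalisation and is propagated
through retro reactions, so the same pair of integers identifies the same bond
in the target, in every intermediate that still contains both atoms, and in the
reactions that eventually separate them.

Two input dialects are supported for declaring constraints on a target:

* explicit pairs of map numbers against a mapped SMILES, e.g.
  ``[CH3:10][C:1](=[O:2])[NH:3][CH3:11]`` with the pair ``(1, 3)``;
* the exclamation-tag dialect, where ``!`` after an atom marks it as part of a
  disconnection site, e.g. ``CC(=O)!N!C``.  Tagged atoms are auto-assigned map
  numbers and every bond between two tagged atoms becomes a bond to break.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ChemError",
    "ParseError",
    "ConstraintError",
    "MappingLossError",
    "BondKey",
    "bond_key",
    "MappedMolecule",
    "ConstraintSet",
    "parse_target",
    "broken_bonds",
    "violates_freeze",
]


class ChemError(ValueError):
    """Base class for molecule/constraint errors."""


class ParseError(ChemError):
    """Raised when a SMILES or tag dialect string cannot be parsed."""


class ConstraintError(ChemError):
    """Raised when a declared bond constraint is inconsistent with the target."""


class MappingLossError(ChemError):
    """Raised when a tracked atom map disappears across a retro step."""


#: An unordered pair of atom-map numbers, stored sorted: (i, j) with i < j.
BondKey = tuple[int, int]


def bond_key(i: int, j: int) -> BondKey:
    """Normalise a pair of map numbers into a canonical :data:`BondKey`.

    Map number 0 is reserved by SMILES for "unmapped" and is rejected.
    """
    i, j = int(i), int(j)
    if i <= 0 or j <= 0:
        raise ConstraintError(f"map numbers must be positive, got ({i}, {j})")
    if i == j:
        raise ConstraintError(f"a bond needs two distinct atoms, got ({i}, {j})")
    return (i, j) if i < j else (j, i)


class MappedMolecule:
    """A molecule whose atoms may carry persistent atom-map numbers.

    Wraps an RDKit molecule.  The mapped SMILES is canonical, so two
    instances built from differently-written SMILES of the same mapped
    molecule compare equal.  ``identity`` strips map numbers (but keeps
    stereochemistry) and is the token used for stock membership: whether a
    molecule is purchasable never depends on the constraint bookkeeping.
    """

    __slots__ = ("rd_mol", "smiles", "_identity")

    def __init__(self, mol: "Chem.Mol | str"):
        if isinstance(mol, str):
            rd = Chem.MolFromSmiles(mol)
            if rd is None:
                raise ParseError(f"invalid SMILES: {mol!r}")
        else:
            rd = mol
        maps = [a.GetAtomMapNum() for a in rd.GetAtoms() if a.GetAtomMapNum() > 0]
        if len(maps) != len(set(maps)):
            dup = sorted(m for m in set(maps) if maps.count(m) > 1)
            raise ParseError(f"duplicate atom map numbers {dup}")
        self.rd_mol = rd
        self.smiles = Chem.MolToSmiles(rd)
        self._identity: Optional[str] = None

    @property
    def map_numbers(self) -> frozenset[int]:
        return frozenset(
            a.GetAtomMapNum() for a in self.rd_mol.GetAtoms() if a.GetAtomMapNum() > 0
        )

    @property
    def identity(self) -> str:
        """Canonical map-free SMILES; the stock lookup token."""
        if self._identity is None:
            stripped = Chem.Mol(self.rd_mol)
            for atom in stripped.GetAtoms():
                atom.SetAtomMapNum(0)
            self._identity = Chem.MolToSmiles(stripped)
        return self._identity

    @property
    def num_heavy_atoms(self) -> int:
        return self.rd_mol.GetNumHeavyAtoms()

    def mapped_bonds(self) -> frozenset[BondKey]:
        """All bonds whose two atoms both carry map numbers."""
        keys = []
        for bond in self.rd_mol.GetBonds():
            i = bond.GetBeginAtom().GetAtomMapNum()
            j = bond.GetEndAtom().GetAtomMapNum()
            if i > 0 and j > 0:
                keys.append(bond_key(i, j))
        return frozenset(keys)

    def has_bond(self, key: BondKey) -> bool:
        return key in self.mapped_bonds()

    def contains_maps(self, key: BondKey) -> bool:
        return set(key) <= self.map_numbers

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MappedMolecule) and self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    def __repr__(self) -> str:
        return f"MappedMolecule({self.smiles!r})"


@dataclass(frozen=True)
class ConstraintSet:
    """User-prompted bond constraints on a target molecule.

    ``bonds_to_break`` are soft: the search favours routes that disconnect
    them but never discards predictions.  ``bonds_to_freeze`` are hard: any
    retro step that breaks one is filtered out.
    """

    bonds_to_break: frozenset[BondKey] = frozenset()
    bonds_to_freeze: frozenset[BondKey] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.bonds_to_break) & set(self.bonds_to_freeze)
        if overlap:
            raise ConstraintError(
                f"bonds declared both to break and to freeze: {sorted(overlap)}"
            )

    @property
    def is_empty(self) -> bool:
        return not self.bonds_to_break and not self.bonds_to_freeze

    def validate_against(self, mol: MappedMolecule) -> None:
        """Check every constrained pair is an existing bond of ``mol``."""
        bonds = mol.mapped_bonds()
        for key in sorted(itertools.chain(self.bonds_to_break, self.bonds_to_freeze)):
            if not mol.contains_maps(key):
                missing = [m for m in key if m not in mol.map_numbers]
                raise ConstraintError(
                    f"constraint {key} references absent map number(s) {missing}"
                )
            if key not in bonds:
                raise ConstraintError(f"atoms {key} are not bonded in the target")

    def union(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(
            self.bonds_to_break | other.bonds_to_break,
            self.bonds_to_freeze | other.bonds_to_freeze,
        )


# --- tag dialect -----------------------------------------------------------

_ATOM_TOKEN = re.compile(
    r"\[[^\]]+\]"  # bracket atom
    r"|Cl|Br"  # two-letter organic subset
    r"|[BCNOSPFI]"  # one-letter organic subset
    r"|[bcnops]"  # aromatic organic subset
)


def _strip_tags(text: str) -> tuple[str, list[int]]:
    """Remove ``!`` tags, returning plain SMILES and tagged atom positions.

    Atom positions are indices in SMILES reading order, which RDKit preserves
    as atom indices when parsing.  A ``!`` tags the current "anchor" atom of
    the SMILES parser state, so ``CC(=O)!N!C`` tags the carbonyl carbon (the
    branch has closed) and the amide nitrogen.
    """
    out: list[str] = []
    tagged: list[int] = []
    anchor = -1  # index of atom a new bond would attach from
    stack: list[int] = []
    n_atoms = 0
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == "!":
            if anchor < 0:
                raise ParseError(f"dangling '!' at position {pos} in {text!r}")
            tagged.append(anchor)
            pos += 1
            continue
        if ch == "(":
            stack.append(anchor)
            out.append(ch)
            pos += 1
            continue
        if ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' in {text!r}")
            anchor = stack.pop()
            out.append(ch)
            pos += 1
            continue
        match = _ATOM_TOKEN.match(text, pos)
        if match:
            anchor = n_atoms
            n_atoms += 1
            out.append(match.group())
            pos = match.end()
            continue
        out.append(ch)
        pos += 1
    return "".join(out), tagged


def parse_target(
    text: str,
    break_pairs: Sequence[tuple[int, int]] = (),
    freeze_pairs: Sequence[tuple[int, int]] = (),
) -> tuple[MappedMolecule, ConstraintSet]:
    """Parse a target SMILES plus its bond constraints.

    ``text`` may carry atom maps, ``!`` tags, or both.  Tagged atoms receive
    auto-assigned map numbers (existing maps are kept) and every bond between
    two tagged atoms becomes a bond to break.  ``break_pairs`` and
    ``freeze_pairs`` are explicit (map_i, map_j) declarations; they are merged
    with the tag-derived constraints.
    """
    plain, tagged_idx = _strip_tags(text)
    rd = Chem.MolFromSmiles(plain)
    if rd is None:
        raise ParseError(f"invalid SMILES: {text!r}")

    # auto-assign map numbers to tagged atoms lacking one
    used = {a.GetAtomMapNum() for a in rd.GetAtoms() if a.GetAtomMapNum() > 0}
    next_map = itertools.count(1)
    for idx in tagged_idx:
        atom = rd.GetAtomWithIdx(idx)
        if atom.GetAtomMapNum() == 0:
            num = next(next_map)
            while num in used:
                num = next(next_map)
            used.add(num)
            atom.SetAtomMapNum(num)

    tag_breaks = set()
    tagged_set = set(tagged_idx)
    for bond in rd.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetIdx() in tagged_set and b.GetIdx() in tagged_set:
            tag_breaks.add(bond_key(a.GetAtomMapNum(), b.GetAtomMapNum()))
    if tagged_idx and not tag_breaks:
        raise ConstraintError(f"'!'-tagged atoms in {text!r} share no bond")

    mol = MappedMolecule(rd)
    constraints = ConstraintSet(
        bonds_to_break=frozenset(tag_breaks | {bond_key(*p) for p in break_pairs}),
        bonds_to_freeze=frozenset(bond_key(*p) for p in freeze_pairs),
    )
    constraints.validate_against(mol)
    return mol, constraints


# --- broken bond detection -------------------------------------------------


def broken_bonds(
    product: MappedMolecule, reactants: Iterable[MappedMolecule]
) -> frozenset[BondKey]:
    """Bonds of ``product`` (between mapped atoms) absent from every reactant.

    A bond (i, j) is broken when no single reactant contains both atoms still
    bonded — including the case where i and j end up in different reactants.
    A change of bond order with the bond retained is not a disconnection.
    Unmapped atoms never participate.
    """
    reactants = list(reactants)
    product_maps = product.map_numbers
    reactant_maps: set[int] = set()
    reactant_bonds: set[BondKey] = set()
    for r in reactants:
        reactant_maps |= r.map_numbers
        reactant_bonds |= r.mapped_bonds()
    lost = product_maps - reactant_maps
    if lost:
        raise MappingLossError(
            f"map numbers {sorted(lost)} present in product "
            f"{product.smiles} but missing from all reactants"
        )
    return frozenset(k for k in product.mapped_bonds() if k not in reactant_bonds)


def violates_freeze(step, freeze: Iterable[BondKey]) -> bool:
    """True iff ``step`` (anything with a ``broken`` set) breaks a frozen bond."""
    return bool(set(step.broken) & set(freeze))
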