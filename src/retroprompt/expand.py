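"""Single-step retro prediction.

Predictions come from a library of retro reaction templates (mapped reaction
SMARTS, product pattern ``>>`` reactant patterns) with prior weights.  Two
expansion policies are built on top of raw template application:

* the *template policy* — rank all successful template applications by their
  normalised prior weights and return the top-k (default 50);
* the *disconnection-aware policy* — for each prompted bond to break that is
  present in the molecule, return up to ``beam`` predictions guaranteed to
  disconnect that bond.  Each prompted bond is handled separately, and the
  policy is silent when the molecule contains none of the prompted bonds.

A multi-expansion strategy concatenates both policies with equal weighting of
their (per-policy normalised) priors.  Bonds to freeze are enforced by a hard
filter that simply discards violating predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (
    BondKey,
    ChemError,
    ConstraintSet,
    MappedMolecule,
    MappingLossError,
    broken_bonds,
    violates_freeze,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RetroTemplate",
    "RetroStep",
    "Stock",
    "load_template_library",
    "save_template_library",
    "apply_template",
    "template_policy",
    "disconnection_policy",
    "multi_expand",
    "frozen_filter",
]

SourcePolicy = Literal["template", "disconnection_aware"]


@dataclass(frozen=True)
class RetroTemplate:
    """A retro reaction template: product pattern ``>>`` reactant patterns."""

    name: str
    retro_smarts: str
    prior_weight: float = 1.0
    reaction_class: str = ""

    def __post_init__(self) -> None:
        if self.prior_weight <= 0:
            raise ValueError(f"template {self.name}: prior_weight must be > 0")
        object.__setattr__(self, "_rxn", None)

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        if self.__dict__.get("_rxn") is None:
            rxn = AllChem.ReactionFromSmarts(self.retro_smarts)
            if rxn is None or rxn.GetNumReactantTemplates() != 1:
                raise ValueError(
                    f"template {self.name}: cannot parse retro SMARTS "
                    f"{self.retro_smarts!r}"
                )
            object.__setattr__(self, "_rxn", rxn)
        return self.__dict__["_rxn"]


@dataclass(frozen=True)
class RetroStep:
    """One retro reaction: a product expanded into a set of precursors."""

    product: MappedMolecule
    reactants: tuple[MappedMolecule, ...]
    prior: float
    source_policy: SourcePolicy
    broken: frozenset[BondKey]
    template_name: str

    def __post_init__(self) -> None:
        if not self.reactants:
            raise ValueError("a retro step needs at least one reactant")

    @property
    def reactant_key(self) -> tuple[str, ...]:
        """Canonical multiset key used for deduplication."""
        return tuple(sorted(r.identity for r in self.reactants))

    def with_prior(self, prior: float) -> "RetroStep":
        return replace(self, prior=prior)


class Stock:
    """The set of purchasable building blocks.

    Membership is by canonical, stereo-aware, map-free SMILES: atom maps and
    constraint bookkeeping never affect whether a molecule is purchasable.
    """

    def __init__(self, smiles: Iterable[str] = ()):
        self._inventory: set[str] = set()
        for smi in smiles:
            self.add(smi)

    def add(self, smiles: str) -> None:
        self._inventory.add(MappedMolecule(smiles).identity)

    def __contains__(self, mol: "MappedMolecule | str") -> bool:
        if isinstance(mol, str):
            mol = MappedMolecule(mol)
        return mol.identity in self._inventory

    def __len__(self) -> int:
        return len(self._inventory)

    def __iter__(self):
        return iter(sorted(self._inventory))

    @classmethod
    def from_file(cls, path: "str | Path") -> "Stock":
        """Load a stock file: one SMILES per line, '#' starts a comment."""
        stock = cls()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                stock.add(line)
        return stock

    def to_file(self, path: "str | Path") -> None:
        Path(path).write_text("".join(f"{smi}\n" for smi in self))


def load_template_library(path: "str | Path") -> list[RetroTemplate]:
    """Read a template library from JSON (list of records) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    return [
        RetroTemplate(
            name=str(rec["name"]),
            retro_smarts=str(rec["retro_smarts"]),
            prior_weight=float(rec.get("prior_weight", 1.0)),
            reaction_class=str(rec.get("reaction_class", "")),
        )
        for rec in records
    ]


def save_template_library(templates: Sequence[RetroTemplate], path: "str | Path") -> None:
    records = [
        {
            "name": t.name,
            "retro_smarts": t.retro_smarts,
            "prior_weight": t.prior_weight,
            "reaction_class": t.reaction_class,
        }
        for t in templates
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def _propagate_maps(source: Chem.Mol, fragment: Chem.Mol) -> Optional[Chem.Mol]:
    """Copy atom maps from ``source`` onto a RunReactants output fragment.

    RDKit records ``react_atom_idx`` on every output atom that originates
    from the input molecule; template-introduced atoms lack it and stay
    unmapped.  Returns None when the fragment fails sanitisation.
    """
    for atom in fragment.GetAtoms():
        props = atom.GetPropsAsDict()
        if "react_atom_idx" in props:
            atom.SetAtomMapNum(source.GetAtomWithIdx(props["react_atom_idx"]).GetAtomMapNum())
        else:
            atom.SetAtomMapNum(0)
    try:
        Chem.SanitizeMol(fragment)
    except Exception:  # pragma: no cover - rdkit raises various exception types
        return None
    return fragment


def apply_template(template: RetroTemplate, mol: MappedMolecule) -> list[RetroStep]:
    """Apply one retro template, one step per distinct embedding.

    The product's map numbers are carried onto the corresponding reactant
    atoms.  Embeddings producing invalid reactants are dropped with a warning;
    duplicate reactant multisets are deduplicated.  Priors are placeholders
    (1.0) until a policy normalises them.
    """
    try:
        outcomes = template.rxn.RunReactants((mol.rd_mol,))
    except Exception:
        logger.warning("template %s failed on %s", template.name, mol.smiles)
        return []
    steps: list[RetroStep] = []
    seen: set[tuple[str, ...]] = set()
    for outcome in outcomes:
        fragments = []
        for frag in outcome:
            frag = _propagate_maps(mol.rd_mol, frag)
            if frag is None:
                fragments = None
                break
            fragments.append(frag)
        if fragments is None:
            logger.warning(
                "template %s produced an invalid reactant for %s; embedding dropped",
                template.name,
                mol.smiles,
            )
            continue
        try:
            reactants = tuple(MappedMolecule(f) for f in fragments)
            broken = broken_bonds(mol, reactants)
        except (MappingLossError, ChemError) as exc:
            logger.warning(
                "template %s on %s: %s; embedding dropped", template.name, mol.smiles, exc
            )
            continue
        step = RetroStep(
            product=mol,
            reactants=reactants,
            prior=1.0,
            source_policy="template",
            broken=broken,
            template_name=template.name,
        )
        if step.reactant_key in seen:
            continue
        seen.add(step.reactant_key)
        steps.append(step)
    return steps


_POLICY_ORDER = {"template": 0, "disconnection_aware": 1}


def _sort_key(weighted: tuple[float, RetroStep]):
    weight, step = weighted
    return (-weight, _POLICY_ORDER[step.source_policy], step.reactant_key, step.template_name)


def _normalise(weighted: list[tuple[float, RetroStep]]) -> list[RetroStep]:
    total = sum(w for w, _ in weighted)
    return [step.with_prior(w / total) for w, step in weighted]


def template_policy(
    mol: MappedMolecule, library: Sequence[RetroTemplate], k: int = 50
) -> list[RetroStep]:
    """Rank all template applications by normalised prior weight; top-k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    weighted: list[tuple[float, RetroStep]] = []
    for template in library:
        for step in apply_template(template, mol):
            weighted.append((template.prior_weight, step))
    if not weighted:
        return []
    weighted.sort(key=_sort_key)
    return _normalise(weighted)[:k]


def disconnection_policy(
    mol: MappedMolecule,
    break_set: Iterable[BondKey],
    library: Sequence[RetroTemplate],
    beam: int = 5,
) -> list[RetroStep]:
    """Disconnection-guaranteed predictions, each prompted bond handled separately.

    Deterministic stand-in for a prompt-conditioned sequence model: template
    applications are filtered to those whose broken-bond set covers the
    prompted bond, keeping up to ``beam`` predictions per bond.  Returns []
    when the molecule contains none of the prompted bonds.
    """
    if beam < 1:
        raise ValueError("beam must be >= 1")
    present = sorted(b for b in break_set if mol.has_bond(b))
    if not present:
        return []
    applications: list[tuple[float, RetroStep]] = []
    for template in library:
        for step in apply_template(template, mol):
            applications.append((template.prior_weight, step))
    applications.sort(key=_sort_key)

    selected: list[tuple[float, RetroStep]] = []
    seen: set[tuple[str, ...]] = set()
    for bond in present:
        per_bond = [(w, s) for w, s in applications if bond in s.broken]
        for weight, step in per_bond[:beam]:
            if step.reactant_key in seen:
                continue
            seen.add(step.reactant_key)
            selected.append((weight, replace(step, source_policy="disconnection_aware")))
    if not selected:
        return []
    selected.sort(key=_sort_key)
    return _normalise(selected)


def multi_expand(
    mol: MappedMolecule,
    constraints: ConstraintSet,
    library: Sequence[RetroTemplate],
    k: int = 50,
    beam: int = 5,
    mode: Literal["standard", "disconnection_aware"] = "standard",
) -> list[RetroStep]:
    """Combine the expansion policies and return the top-k predictions.

    ``standard`` mode is exactly the template policy.  In
    ``disconnection_aware`` mode the two policies' outputs are concatenated
    with their per-policy normalised priors weighted equally, sorted by prior,
    and deduplicated on the canonical reactant multiset (higher prior wins;
    at equal priors, template predictions sort first).
    """
    if mode == "standard":
        return template_policy(mol, library, k)
    steps = template_policy(mol, library, k) + disconnection_policy(
        mol, constraints.bonds_to_break, library, beam
    )
    steps.sort(
        key=lambda s: (-s.prior, _POLICY_ORDER[s.source_policy], s.reactant_key, s.template_name)
    )
    deduped: list[RetroStep] = []
    seen: set[tuple[str, ...]] = set()
    for step in steps:
        if step.reactant_key in seen:
            continue
        seen.add(step.reactant_key)
        deduped.append(step)
    return deduped[:k]


def frozen_filter(steps: Sequence[RetroStep], freeze: Iterable[BondKey]) -> list[RetroStep]:
    """Discard every prediction that breaks a frozen bond; order preserved."""
    freeze = frozenset(freeze)
    if not freeze:
        return list(steps)
    return [s for s in steps if not violates_freeze(s, freeze)]
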