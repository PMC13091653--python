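"""Reaction parsing, canonicalization, tokenization, and tabular I/O.

Reactions are handled as reaction SMILES (``reactants>>products``, components
dot-joined; the three-field ``reactants>agents>products`` dialect is accepted
and the middle field kept as agents). Canonicalization strips atom-map numbers,
canonicalizes every component with RDKit, and sorts components lexicographically
within each side so that string equality of the canonical form detects duplicate
reactions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "Reaction",
    "TokenSequence",
    "ReactionParseError",
    "TokenizationError",
    "canonicalize_smiles",
    "canonicalize_reaction",
    "reverse_reaction",
    "tokenize",
    "tokenize_smiles",
    "read_reaction_table",
    "write_reaction_table",
]


class ReactionParseError(ValueError):
    """Raised when a reaction SMILES or one of its components cannot be parsed."""


class TokenizationError(ValueError):
    """Raised when a character in a reaction SMILES is not covered by the token regex."""


@dataclass(frozen=True)
class Molecule:
    """A single chemical species with its canonical SMILES and RDKit mol handle."""

    smiles: str
    mol: Chem.Mol = field(compare=False, repr=False, hash=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ReactionParseError(f"unparsable SMILES component: {smiles!r}")
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
        return cls(smiles=Chem.MolToSmiles(mol), mol=mol)


@dataclass(frozen=True)
class Reaction:
    """A canonicalized reaction: reactants >> products, optional agents and label."""

    id: str
    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    agents: tuple[Molecule, ...] = ()
    label: Optional[Union[str, int]] = None
    ec: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ReactionParseError(
                f"reaction {self.id!r} needs at least one reactant and one product"
            )

    @property
    def smiles(self) -> str:
        """Canonical ``reactants>>products`` string (agents not serialized)."""
        left = ".".join(m.smiles for m in self.reactants)
        right = ".".join(m.smiles for m in self.products)
        return f"{left}>>{right}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


@dataclass(frozen=True)
class TokenSequence:
    """Ordered SMILES tokens of a reaction with the ``>>`` separator position."""

    tokens: tuple[str, ...]
    separator_index: int

    def join(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def canonicalize_smiles(smiles: str) -> str:
    """Canonical SMILES of a single component with atom maps removed."""
    return Molecule.from_smiles(smiles).smiles


def _parse_side(side: str) -> tuple[Molecule, ...]:
    mols = [Molecule.from_smiles(part) for part in side.split(".") if part]
    return tuple(sorted(mols, key=lambda m: m.smiles))


def canonicalize_reaction(
    raw_reaction_smiles: str,
    id: str = "",
    label: Optional[Union[str, int]] = None,
    ec: Optional[str] = None,
) -> Reaction:
    """Parse and canonicalize a reaction SMILES.

    Accepts ``reactants>>products`` or the three-field ``reactants>agents>products``
    dialect. Atom maps are stripped, every component is canonicalized, and
    components are sorted lexicographically within each side, so two reactions
    that differ only in component order or atom mapping produce the same string.
    """
    raw = raw_reaction_smiles.strip()
    if ">>" in raw:
        parts = raw.split(">>")
        if len(parts) != 2:
            raise ReactionParseError(f"expected a single '>>' in {raw!r}")
        left, mid, right = parts[0], "", parts[1]
    else:
        parts = raw.split(">")
        if len(parts) != 3:
            raise ReactionParseError(
                f"expected 'reactants>>products' or 'reactants>agents>products', got {raw!r}"
            )
        left, mid, right = parts
    reactants = _parse_side(left)
    products = _parse_side(right)
    agents = _parse_side(mid) if mid else ()
    return Reaction(
        id=id or raw, reactants=reactants, products=products, agents=agents,
        label=label, ec=ec,
    )


def reverse_reaction(reaction: Reaction) -> Reaction:
    """Swap reactant and product sides (directionality diagnostic)."""
    return Reaction(
        id=f"{reaction.id}::reversed",
        reactants=reaction.products,
        products=reaction.reactants,
        agents=reaction.agents,
        label=reaction.label,
        ec=reaction.ec,
    )


# Regex SMILES tokenizer following the published reaction-transformer convention:
# bracket atoms, two-letter halogens, the '>>' separator and two-digit ring
# closures are single tokens; everything else is one character.
SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+\]|>>|Br|Cl|%\d{2}|[A-Za-z]|\d|\(|\)|\.|=|#|\-|\+|\\|/|:|~|@|\?|\*|\$|>)"
)
_TOKEN_RE = re.compile(SMILES_TOKEN_PATTERN)


def tokenize_smiles(smiles: str) -> list[str]:
    """Tokenize a (reaction) SMILES string; raises on uncovered characters."""
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        match = _TOKEN_RE.match(smiles, pos)
        if match is None:
            raise TokenizationError(
                f"character {smiles[pos]!r} at position {pos} of {smiles!r} "
                "is not a valid SMILES token"
            )
        tokens.append(match.group(0))
        pos = match.end()
    return tokens


def tokenize(reaction: Union[Reaction, str]) -> TokenSequence:
    """Tokenize a reaction into SMILES tokens with the separator marked."""
    smiles = reaction.smiles if isinstance(reaction, Reaction) else reaction
    tokens = tokenize_smiles(smiles)
    try:
        sep = tokens.index(">>")
    except ValueError as exc:
        raise TokenizationError(f"no '>>' separator in {smiles!r}") from exc
    return TokenSequence(tokens=tuple(tokens), separator_index=sep)


def _infer_sep(path: Union[str, Path]) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_reaction_table(
    path: Union[str, Path],
    smiles_col: str = "reaction_smiles",
    id_col: str = "id",
    label_col: str = "label",
    ec_col: str = "ec",
    sep: Optional[str] = None,
) -> list[Reaction]:
    """Read reactions from a TSV/CSV table with a header row.

    Requires ``id`` and ``reaction_smiles`` columns (names configurable);
    ``label`` and ``ec`` are optional.
    """
    df = pd.read_csv(path, sep=sep or _infer_sep(path), dtype=str)
    for col in (id_col, smiles_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    reactions = []
    for _, row in df.iterrows():
        reactions.append(
            canonicalize_reaction(
                row[smiles_col],
                id=str(row[id_col]),
                label=row[label_col] if label_col in df.columns else None,
                ec=row[ec_col] if ec_col in df.columns else None,
            )
        )
    return reactions


def write_reaction_table(
    reactions: Sequence[Reaction],
    path: Union[str, Path],
    sep: Optional[str] = None,
) -> None:
    """Write reactions as a TSV/CSV table (id, reaction_smiles, label?, ec?)."""
    records = {
        "id": [r.id for r in reactions],
        "reaction_smiles": [r.smiles for r in reactions],
    }
    if any(r.label is not None for r in reactions):
        records["label"] = [r.label for r in reactions]
    if any(r.ec is not None for r in reactions):
        records["ec"] = [r.ec for r in reactions]
    pd.DataFrame(records).to_csv(path, sep=sep or _infer_sep(path), index=False)


def deduplicate(reactions: Iterable[Reaction]) -> list[Reaction]:
    """Drop reactions identical up to component order and atom maps."""
    seen: set[str] = set()
    unique = []
    for r in reactions:
        if r.smiles not in seen:
            seen.add(r.smiles)
            unique.append(r)
    return unique
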