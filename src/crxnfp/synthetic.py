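"""Synthetic reaction corpora: template-labeled reactions without any downloads.

Scaffold molecules (substituted benzenes and short functionalized chains) are
generated compositionally, then named transformation templates — RDKit
reaction SMARTS covering hydrolysis, oxidation/reduction and substitution
chemistry reminiscent of environmental biotransformations — are applied to
matching scaffolds. Each template carries a pseudo-EC label with real EC
superclass semantics (1.x oxidoreductions, 3.x hydrolyses, ...), so the
template name doubles as a classification label and the pseudo-EC exercises
the hierarchical scoring logic end to end.

Reactions generated from one template share a reaction center, hence a high
differential-fingerprint Tanimoto within the template and a low one across
templates — the structural premise that makes the contrastive target
informative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import Molecule, Reaction, canonicalize_reaction, write_reaction_table
from .fingerprints import drfp
from .pairs import BinScheme, ReactionPair, sample_pairs, write_pairs

__all__ = [
    "ReactionTemplate",
    "DEFAULT_TEMPLATES",
    "generate_scaffolds",
    "apply_template",
    "make_labeled_corpus",
    "make_benchmark",
]


@dataclass(frozen=True)
class ReactionTemplate:
    """A named graph-edit transformation with a pseudo-EC label."""

    name: str
    smarts: str
    pseudo_ec: str
    # substituent attached to scaffold cores to guarantee a reaction site
    trigger_group: str
    # "aromatic" when the trigger only reacts on an aromatic carbon
    core_kind: str = "any"

    def rdkit_reaction(self):
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise ValueError(f"invalid reaction SMARTS for template {self.name!r}")
        return rxn


DEFAULT_TEMPLATES: tuple[ReactionTemplate, ...] = (
    ReactionTemplate(
        name="ester_hydrolysis",
        smarts="[C:1](=[O:2])[O:3][CX4:4]>>[C:1](=[O:2])[OH].[OX2H1:3][C:4]",
        pseudo_ec="3.1.1.1",
        trigger_group="C(=O)OC",
    ),
    ReactionTemplate(
        name="amide_hydrolysis",
        smarts="[C:1](=[O:2])[NX3:3]>>[C:1](=[O:2])[OH].[NX3:3]",
        pseudo_ec="3.5.1.4",
        trigger_group="C(=O)N(C)C",
    ),
    ReactionTemplate(
        name="alcohol_oxidation",
        smarts="[CX4;H2:1][OX2H1:2]>>[CX3;H1:1]=[OX1:2]",
        pseudo_ec="1.1.1.1",
        trigger_group="CO",
    ),
    ReactionTemplate(
        name="nitro_reduction",
        smarts="[NX3+:1](=[O:2])[O-:3]>>[NX3;H2:1]",
        pseudo_ec="1.7.1.16",
        trigger_group="[N+](=O)[O-]",
    ),
    ReactionTemplate(
        name="aromatic_dehalogenation",
        smarts="[c:1][Cl:2]>>[c:1][OH]",
        pseudo_ec="3.8.1.5",
        trigger_group="Cl",
        core_kind="aromatic",
    ),
    ReactionTemplate(
        name="o_demethylation",
        smarts="[c:1][OX2:2][CH3:3]>>[c:1][OX2H1:2]",
        pseudo_ec="1.14.13.25",
        trigger_group="OC",
        core_kind="aromatic",
    ),
)

# Decoration pool for scaffold cores; chemically inert w.r.t. the templates
# above except where a trigger group is placed deliberately.
_NEUTRAL_SUBSTITUENTS = (
    "", "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "F", "C(F)(F)F", "CCF", "C#N", "CCCC",
)
# Slot tags {a}/{b}/{c} sit where a parenthesized branch is syntactically valid;
# the trigger group always occupies slot a.
_AROMATIC_CORES = (
    "c1ccc{a}cc1{b}",
    "c1ccc{a}c{b}c1",
    "c1cc{a}cc{b}c1{c}",
    "c1cc{a}ccc1C{b}",
    "c1ccc(CC{a})cc1{b}",
    "Cc1cc{a}ccc1{b}",
    "c1cc{a}c{b}cc1C{c}",
)
_ALIPHATIC_CORES = (
    "C{a}CC{b}",
    "CC{a}CC{b}",
    "CCC{a}CC{b}",
    "C{a}C(C)C{b}",
    "CC(C){a}CC{b}",
)


def _assemble(core: str, subs: Sequence[str]) -> Optional[str]:
    smiles = core
    for tag, sub in zip(("{a}", "{b}", "{c}"), subs):
        smiles = smiles.replace(tag, f"({sub})" if sub else "")
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def generate_scaffolds(
    n: int, seed: int = 0, required_group: str = "", core_kind: str = "any"
) -> list[Molecule]:
    """Deterministically generate ``n`` distinct valid scaffold molecules.

    With ``required_group`` set, every scaffold carries that substituent on its
    first decoration site, guaranteeing a match for the owning template;
    ``core_kind="aromatic"`` restricts the cores to substituted benzenes for
    triggers that only react on aromatic carbons.
    """
    rng = np.random.default_rng(seed)
    cores = _AROMATIC_CORES if core_kind == "aromatic" else _AROMATIC_CORES + _ALIPHATIC_CORES
    scaffolds: list[Molecule] = []
    seen: set[str] = set()
    attempts = 0
    while len(scaffolds) < n and attempts < 500 * max(n, 1):
        attempts += 1
        core = cores[rng.integers(len(cores))]
        first = required_group or _NEUTRAL_SUBSTITUENTS[rng.integers(len(_NEUTRAL_SUBSTITUENTS))]
        rest = [
            _NEUTRAL_SUBSTITUENTS[rng.integers(len(_NEUTRAL_SUBSTITUENTS))]
            for _ in range(2)
        ]
        smiles = _assemble(core, (first, *rest))
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        scaffolds.append(Molecule.from_smiles(smiles))
    if len(scaffolds) < n:
        raise RuntimeError(f"could only generate {len(scaffolds)} of {n} scaffolds")
    return scaffolds


def apply_template(
    mol: Molecule, template: ReactionTemplate, reaction_id: str = ""
) -> Optional[Reaction]:
    """Apply a template to a scaffold; None when the scaffold does not match.

    Only the first product set is used, so one scaffold yields one reaction.
    Degenerate outcomes (product side identical to the reactant) are dropped.
    """
    rxn = template.rdkit_reaction()
    product_sets = rxn.RunReactants((mol.mol,))
    if not product_sets:
        return None
    products = []
    try:
        for prod in product_sets[0]:
            Chem.SanitizeMol(prod)
            products.append(Chem.MolToSmiles(prod))
    except Exception:
        return None
    smiles = f"{mol.smiles}>>{'.'.join(products)}"
    reaction = canonicalize_reaction(
        smiles, id=reaction_id or f"{template.name}:{mol.smiles}",
        label=template.name, ec=template.pseudo_ec,
    )
    if {m.smiles for m in reaction.reactants} == {m.smiles for m in reaction.products}:
        return None
    if drfp(reaction, max_radius=2, n_bits=2048).degenerate:
        return None
    return reaction


def make_labeled_corpus(
    n_per_class: int = 30,
    templates: Sequence[ReactionTemplate] = DEFAULT_TEMPLATES,
    seed: int = 0,
) -> list[Reaction]:
    """Template-labeled reaction corpus, ``n_per_class`` reactions per template."""
    corpus: list[Reaction] = []
    for t_idx, template in enumerate(templates):
        scaffolds = generate_scaffolds(
            3 * n_per_class,
            seed=seed * 1009 + t_idx,
            required_group=template.trigger_group,
            core_kind=template.core_kind,
        )
        count = 0
        for s_idx, scaffold in enumerate(scaffolds):
            reaction = apply_template(
                scaffold, template, reaction_id=f"{template.name}_{count:04d}"
            )
            if reaction is None:
                continue
            corpus.append(reaction)
            count += 1
            if count >= n_per_class:
                break
        if count < n_per_class:
            raise RuntimeError(
                f"template {template.name!r}: only {count} of {n_per_class} reactions"
            )
    return corpus


def make_benchmark(
    n_per_class: int = 30,
    templates: Sequence[ReactionTemplate] = DEFAULT_TEMPLATES,
    seed: int = 0,
    pair_scheme: Optional[BinScheme] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Full desk-scale benchmark: labeled corpus, contrastive pairs, reference set.

    Returns a dict with the labeled ``reactions``, the stratified ``pairs``
    and the pseudo-EC ``reference`` annotations; with ``out_dir`` set, also
    writes reactions.tsv, pairs.tsv and reference.tsv.
    """
    from .enzyme import AnnotatedReaction, ECNumber

    reactions = make_labeled_corpus(n_per_class, templates, seed)
    scheme = pair_scheme or BinScheme.desk_scale(quota=10)
    pairs = sample_pairs(reactions, scheme, seed=seed)
    reference = [
        AnnotatedReaction(
            reaction=r, ec=ECNumber.parse(r.ec), source_id=r.id
        )
        for r in reactions
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reaction_table(reactions, out / "reactions.tsv")
        write_pairs(pairs, out / "pairs.tsv")
        import pandas as pd

        pd.DataFrame(
            {
                "source_id": [a.source_id for a in reference],
                "reaction_smiles": [a.reaction.smiles for a in reference],
                "ec": [str(a.ec) for a in reference],
                "uniprot_accessions": ["" for _ in reference],
            }
        ).to_csv(out / "reference.tsv", sep="\t", index=False)
    return {"reactions": reactions, "pairs": pairs, "reference": reference}
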