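"""Similarity-based enzyme association and hierarchical EC scoring.

A query reaction is embedded, compared against an EC/protein-annotated
reference set (e.g. Rhea-derived) by cosine similarity, and associated with
the top-k references above a similarity threshold (default k=5, cosine > 0.5).
Queries with no reference above the threshold get the explicit
``no_analogous_reaction`` status instead of a forced prediction.

EC numbers are hierarchical (class.subclass.sub-subclass.serial); trailing
fields may be absent or the wildcard "-". Scoring at level L compares the
first L fields, except that a reference specified only to depth d < L is
compared at depth d (a reference "6.2.1" accepts the prediction "6.2.1.40" at
level 3 and below). Composite references ("x AND y") count as correct when any
alternative matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem_io import Reaction

__all__ = [
    "ECNumber",
    "ECReference",
    "AnnotatedReaction",
    "AssociationResult",
    "Neighbor",
    "EnzymeAssociator",
    "ec_match",
    "score_ec_predictions",
    "load_fluorinated_benchmark",
    "score_benchmark_table",
]

DEFAULT_K = 5
DEFAULT_THRESHOLD = 0.5
NO_PREDICTION = "no_analogous_reaction"


@dataclass(frozen=True)
class ECNumber:
    """A 1-4 field EC number; trailing fields may be wildcard/absent (None)."""

    fields: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 4:
            raise ValueError("EC number needs 1-4 fields")
        seen_gap = False
        for f in self.fields:
            if f is None:
                seen_gap = True
            else:
                if seen_gap:
                    raise ValueError("specified EC field after a wildcard")
                if f <= 0:
                    raise ValueError("EC fields must be positive integers")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        fields = tuple(None if p in ("-", "") else int(p) for p in parts)
        return cls(fields=fields)

    @property
    def depth(self) -> int:
        """Number of leading specified fields."""
        d = 0
        for f in self.fields:
            if f is None:
                break
            d += 1
        return d

    def __str__(self) -> str:
        return ".".join("-" if f is None else str(f) for f in self.fields)


@dataclass(frozen=True)
class ECReference:
    """One or more acceptable EC alternatives (the "AND"-joined composites)."""

    alternatives: tuple[ECNumber, ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("ECReference needs at least one alternative")

    @classmethod
    def parse(cls, text: str) -> "ECReference":
        parts = [p.strip() for p in text.split("AND")]
        return cls(alternatives=tuple(ECNumber.parse(p) for p in parts if p))

    def __str__(self) -> str:
        return " AND ".join(str(a) for a in self.alternatives)


@dataclass(frozen=True)
class AnnotatedReaction:
    """A reference reaction with its EC annotation and optional accessions."""

    reaction: Reaction
    ec: ECNumber
    protein_accessions: tuple[str, ...] = ()
    source_id: str = ""


@dataclass(frozen=True)
class Neighbor:
    source_id: str
    cosine: float
    ec: ECNumber


@dataclass(frozen=True)
class AssociationResult:
    """Ranked surviving neighbors of one query, or the no-analog status."""

    query_id: str
    neighbors: tuple[Neighbor, ...]

    def __post_init__(self) -> None:
        cosines = [n.cosine for n in self.neighbors]
        if cosines != sorted(cosines, reverse=True):
            raise ValueError("neighbors must be sorted by descending cosine")

    @property
    def status(self) -> str:
        return "predicted" if self.neighbors else NO_PREDICTION


def ec_match(
    predicted: Optional[ECNumber],
    reference: Union[ECReference, ECNumber, str],
    level: int,
) -> bool:
    """True iff the prediction matches some reference alternative at ``level``.

    The comparison depth is ``min(level, reference depth)``: a reference
    specified only to depth d scores predictions at depth d for all levels
    >= d. The prediction must itself be specified to the comparison depth.
    """
    if not 1 <= level <= 4:
        raise ValueError("level must be in 1..4")
    if predicted is None:
        return False
    if isinstance(reference, str):
        reference = ECReference.parse(reference)
    if isinstance(reference, ECNumber):
        reference = ECReference(alternatives=(reference,))
    for alt in reference.alternatives:
        depth = min(level, alt.depth)
        if depth == 0 or predicted.depth < depth:
            continue
        if predicted.fields[:depth] == alt.fields[:depth]:
            return True
    return False


def score_ec_predictions(
    rows: Sequence[tuple[Union[ECReference, str], Optional[Union[ECNumber, str]]]],
    level: int,
) -> float:
    """Accuracy percent of EC predictions at a hierarchy level.

    Each row is (reference, prediction); missing predictions (None) stay in
    the denominator as errors. Returns 100 * matches / rows.
    """
    if not rows:
        raise ValueError("no rows to score")
    n_match = 0
    for reference, predicted in rows:
        if isinstance(predicted, str):
            predicted = ECNumber.parse(predicted)
        if ec_match(predicted, reference, level):
            n_match += 1
    return 100.0 * n_match / len(rows)


class EnzymeAssociator:
    """Fit/predict-shaped cosine-similarity association against a reference set.

    ``fit`` stores reference embeddings plus annotations; ``associate`` returns
    the top-k neighbors above the threshold for each query embedding, and
    ``predict_ec`` reduces an association to a single EC (top-hit rule by
    default, majority vote at a level as the alternative).
    """

    def __init__(self, k: int = DEFAULT_K, threshold: float = DEFAULT_THRESHOLD):
        if k < 1:
            raise ValueError("k must be >= 1")
        if not -1.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [-1, 1]")
        self.k = k
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "threshold": self.threshold}

    def set_params(self, **params) -> "EnzymeAssociator":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self,
        reference_embeddings: np.ndarray,
        annotations: Sequence[AnnotatedReaction],
    ) -> "EnzymeAssociator":
        X = np.asarray(reference_embeddings, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("empty reference index")
        if X.shape[0] != len(annotations):
            raise ValueError("one annotation per reference embedding required")
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-norm reference embedding")
        self.X_ = X / norms
        self.annotations_ = tuple(annotations)
        return self

    def associate_one(self, query_embedding: np.ndarray, query_id: str = "") -> AssociationResult:
        if not hasattr(self, "X_"):
            raise RuntimeError("associator is not fitted")
        q = np.asarray(query_embedding, dtype=float)
        nq = np.linalg.norm(q)
        if nq == 0:
            raise ValueError("zero-norm query embedding")
        sims = self.X_ @ (q / nq)
        order = np.argsort(-sims, kind="stable")[: self.k]
        neighbors = tuple(
            Neighbor(
                source_id=self.annotations_[i].source_id or str(i),
                cosine=float(sims[i]),
                ec=self.annotations_[i].ec,
            )
            for i in order
            if sims[i] > self.threshold
        )
        return AssociationResult(query_id=query_id, neighbors=neighbors)

    def associate(
        self, query_embeddings: np.ndarray, query_ids: Optional[Sequence[str]] = None
    ) -> list[AssociationResult]:
        Q = np.atleast_2d(np.asarray(query_embeddings, dtype=float))
        ids = query_ids or [str(i) for i in range(len(Q))]
        return [self.associate_one(q, qid) for q, qid in zip(Q, ids)]

    @staticmethod
    def predict_ec(
        result: AssociationResult, rule: str = "top_hit", vote_level: int = 3
    ) -> Optional[ECNumber]:
        """Single EC from an association: top-hit (default) or majority vote.

        The vote rule tallies neighbor ECs truncated to ``vote_level`` fields
        and returns the top-ranked neighbor's full EC among the winning group.
        Returns None for the no-analog status.
        """
        if not result.neighbors:
            return None
        if rule == "top_hit":
            return result.neighbors[0].ec
        if rule == "majority":
            tally: dict[tuple, int] = {}
            for n in result.neighbors:
                key = n.ec.fields[: min(vote_level, n.ec.depth)]
                tally[key] = tally.get(key, 0) + 1
            best = max(tally.values())
            winners = {k for k, c in tally.items() if c == best}
            for n in result.neighbors:
                if n.ec.fields[: min(vote_level, n.ec.depth)] in winners:
                    return n.ec
        raise ValueError(f"unknown aggregation rule {rule!r}")


def build_reference_index(
    annotated_reactions: Sequence[AnnotatedReaction],
    encoder,
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
) -> EnzymeAssociator:
    """Embed annotated reference reactions and fit an :class:`EnzymeAssociator`."""
    embeddings = encoder.transform([a.reaction for a in annotated_reactions])
    return EnzymeAssociator(k=k, threshold=threshold).fit(embeddings, annotated_reactions)


def read_reference_table(
    path: Union[str, Path],
    smiles_col: str = "reaction_smiles",
    ec_col: str = "ec",
    id_col: str = "source_id",
    accessions_col: str = "uniprot_accessions",
) -> list[AnnotatedReaction]:
    """Read a user-supplied annotated reference TSV (Rhea-like)."""
    from .chem_io import canonicalize_reaction

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_col, smiles_col, ec_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    out = []
    for _, row in df.iterrows():
        accessions: tuple[str, ...] = ()
        if accessions_col in df.columns and isinstance(row[accessions_col], str):
            accessions = tuple(a for a in row[accessions_col].split(";") if a)
        out.append(
            AnnotatedReaction(
                reaction=canonicalize_reaction(row[smiles_col], id=str(row[id_col])),
                ec=ECNumber.parse(row[ec_col]),
                protein_accessions=accessions,
                source_id=str(row[id_col]),
            )
        )
    return out


# -- packaged fluorinated-compound benchmark -----------------------------


def load_fluorinated_benchmark() -> pd.DataFrame:
    """The packaged 23-reaction fluorinated-compound benchmark table.

    Columns: reaction (description), ec_reference, and the printed predictions
    of three tools (claire, theia, crxnfp); empty prediction cells mean the
    tool returned no prediction for that reaction.
    """
    with resources.files("crxnfp.data").joinpath("table3_fluorinated.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def score_benchmark_table(
    table: Optional[pd.DataFrame] = None,
    column: str = "crxnfp",
    level: int = 3,
) -> float:
    """Accuracy percent of one prediction column of the benchmark table."""
    df = load_fluorinated_benchmark() if table is None else table
    if column not in df.columns:
        raise ValueError(f"no prediction column {column!r}")
    rows = []
    for _, row in df.iterrows():
        cell = row[column]
        predicted = None if not isinstance(cell, str) or not cell.strip() else cell
        rows.append((ECReference.parse(row["ec_reference"]), predicted))
    return score_ec_predictions(rows, level)
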