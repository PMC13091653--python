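"""Contrastive pair construction: transformed Tanimoto targets and binned sampling.

Raw drfp Tanimoto similarities between random reaction pairs pile up near zero,
which gives a regression target with poor resolution where most of the data
lives. The transformed score

    target = 1 - exp(-5 * tanimoto)

shifts the distribution rightward while staying in [0, 1): 0 maps to 0 and
1 maps to 1 - e^-5 ≈ 0.9933. Training pairs are sampled into seven bins on the
transformed scale (0–0.1 … 0.5–0.6 plus a wide 0.6–1.0 tail bin that receives a
4x quota, because highly similar pairs are rare) so the target distribution is
roughly uniform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem_io import Reaction
from .fingerprints import BinaryFingerprint, drfp, tanimoto

__all__ = [
    "TRANSFORM_COEFFICIENT",
    "ReactionPair",
    "BinScheme",
    "transform_score",
    "inverse_transform_score",
    "sample_pairs",
    "pair_stats",
    "pairs_to_frame",
    "write_pairs",
    "read_pairs",
]

TRANSFORM_COEFFICIENT = 5.0

# Seven bins on the transformed scale; the last bin is wider and oversampled.
DEFAULT_BOUNDARIES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0)
FULL_SCALE_QUOTAS = (100_000,) * 6 + (400_000,)


def transform_score(tanimoto_raw: float) -> float:
    """Exponential rescaling 1 - exp(-5 t) of a raw Tanimoto similarity."""
    if not 0.0 <= tanimoto_raw <= 1.0:
        raise ValueError(f"Tanimoto similarity must be in [0, 1], got {tanimoto_raw}")
    return 1.0 - math.exp(-TRANSFORM_COEFFICIENT * tanimoto_raw)


def inverse_transform_score(target: float) -> float:
    """Recover the raw Tanimoto from a transformed score."""
    if not 0.0 <= target < 1.0:
        raise ValueError(f"transformed score must be in [0, 1), got {target}")
    return -math.log1p(-target) / TRANSFORM_COEFFICIENT


@dataclass(frozen=True)
class ReactionPair:
    """An unordered reaction pair with its raw and transformed similarity."""

    id_a: str
    id_b: str
    smiles_a: str
    smiles_b: str
    tanimoto_raw: float
    target: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair forbidden: {self.id_a!r}")
        expected = transform_score(self.tanimoto_raw)
        if abs(self.target - expected) > 1e-12:
            raise ValueError(
                f"target {self.target} inconsistent with tanimoto {self.tanimoto_raw}"
            )


@dataclass(frozen=True)
class BinScheme:
    """Bin boundaries (transformed scale) and per-bin pair quotas."""

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    quotas: tuple[int, ...] = field(default=(10,) * 6 + (40,))

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("bin boundaries must be strictly increasing")
        if len(self.quotas) != len(self.boundaries) - 1:
            raise ValueError("need one quota per bin")
        if any(q <= 0 for q in self.quotas):
            raise ValueError("quotas must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.quotas)

    def bin_of(self, target: float) -> Optional[int]:
        """Half-open bins [lo, hi); the last bin is closed at the top."""
        bounds = self.boundaries
        for i in range(self.n_bins):
            lo, hi = bounds[i], bounds[i + 1]
            if lo <= target < hi or (i == self.n_bins - 1 and target == hi):
                return i
        return None

    @classmethod
    def desk_scale(cls, quota: int = 10, last_bin_factor: int = 4) -> "BinScheme":
        return cls(quotas=(quota,) * 6 + (quota * last_bin_factor,))

    @classmethod
    def full_scale(cls) -> "BinScheme":
        return cls(quotas=FULL_SCALE_QUOTAS)


def sample_pairs(
    reactions: Sequence[Reaction],
    scheme: BinScheme = BinScheme(),
    seed: int = 0,
    max_radius: int = 2,
    n_bits: int = 2048,
    max_draw_factor: int = 50,
) -> list[ReactionPair]:
    """Rejection-sample reaction pairs into the transformed-score bins.

    Degenerate reactions (empty drfp) are excluded up front. Unordered pairs are
    deduplicated globally; a bin whose quota cannot be filled within
    ``max_draw_factor`` times the total quota of draws is left short with a
    warning. Fixed seed ⇒ byte-identical output.
    """
    fps: list[BinaryFingerprint] = [drfp(r, max_radius, n_bits) for r in reactions]
    keep = [i for i, fp in enumerate(fps) if not fp.degenerate]
    if len(keep) < 2:
        raise ValueError("need at least two non-degenerate reactions to sample pairs")

    rng = np.random.default_rng(seed)
    counts = [0] * scheme.n_bins
    quotas = list(scheme.quotas)
    seen: set[tuple[int, int]] = set()
    pairs: list[ReactionPair] = []
    max_draws = max_draw_factor * sum(quotas)
    n_possible = len(keep) * (len(keep) - 1) // 2

    draws = 0
    while draws < max_draws and any(c < q for c, q in zip(counts, quotas)):
        if len(seen) >= n_possible:
            break
        draws += 1
        i, j = rng.choice(len(keep), size=2, replace=False)
        a, b = keep[i], keep[j]
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        t_raw = tanimoto(fps[key[0]], fps[key[1]])
        target = transform_score(t_raw)
        b_idx = scheme.bin_of(target)
        if b_idx is None or counts[b_idx] >= quotas[b_idx]:
            continue
        counts[b_idx] += 1
        ra, rb = reactions[key[0]], reactions[key[1]]
        pairs.append(
            ReactionPair(
                id_a=ra.id, id_b=rb.id, smiles_a=ra.smiles, smiles_b=rb.smiles,
                tanimoto_raw=t_raw, target=target,
            )
        )

    short = [i for i, (c, q) in enumerate(zip(counts, quotas)) if c < q]
    if short:
        warnings.warn(
            f"bins {short} under quota after {draws} draws "
            f"(counts={counts}, quotas={quotas}); corpus too sparse",
            stacklevel=2,
        )
    return pairs


def pairs_to_frame(pairs: Sequence[ReactionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id_a": [p.id_a for p in pairs],
            "id_b": [p.id_b for p in pairs],
            "smiles_a": [p.smiles_a for p in pairs],
            "smiles_b": [p.smiles_b for p in pairs],
            "tanimoto": [p.tanimoto_raw for p in pairs],
            "target": [p.target for p in pairs],
        }
    )


def write_pairs(pairs: Sequence[ReactionPair], path: Union[str, Path]) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_pairs(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("smiles_a", "smiles_b", "target"):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    return df


def pair_stats(
    pairs: Sequence[ReactionPair], bucket_width: float = 0.05
) -> pd.DataFrame:
    """Histogram of raw and transformed similarities in fixed-width buckets."""
    edges = np.arange(0.0, 1.0 + bucket_width / 2, bucket_width)
    raw = np.asarray([p.tanimoto_raw for p in pairs])
    tgt = np.asarray([p.target for p in pairs])
    raw_counts, _ = np.histogram(raw, bins=edges)
    tgt_counts, _ = np.histogram(tgt, bins=edges)
    return pd.DataFrame(
        {
            "bucket_lo": edges[:-1],
            "bucket_hi": edges[1:],
            "tanimoto_count": raw_counts,
            "target_count": tgt_counts,
        }
    )
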