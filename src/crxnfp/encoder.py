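"""Contrastive reaction encoder: sklearn-style estimator over the NumPy transformer.

``ContrastiveReactionEncoder`` is a ``TransformerMixin`` estimator:

* ``fit(pairs)`` contrastively fine-tunes the encoder so that the cosine
  similarity of pooled reaction embeddings regresses onto transformed drfp
  Tanimoto targets (MSE objective, Adam, linear warmup/decay schedule,
  early stopping on validation MSE).
* ``transform(reactions)`` produces one dense fingerprint per reaction
  (hidden_size-dimensional; 256 at full scale).

Defaults mirror the full-scale recipe: 12 layers, hidden 256, FFN 512,
4 heads, mean pooling, max LR 5e-5 with 10% warmup, 5 epochs, batch 32,
patience 200 steps. Desk-scale work shrinks ``n_layers``/``hidden_size``;
everything else is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import Reaction, reverse_reaction, tokenize_smiles
from .nn import (
    CLS_TOKEN,
    AdamOptimizer,
    TransformerEncoderModel,
    Vocabulary,
    WarmupLinearSchedule,
    cosine,
    cosine_mse_loss,
    mean_pool,
)
from .pairs import ReactionPair, pairs_to_frame

__all__ = [
    "ContrastiveReactionEncoder",
    "ReactionEmbedding",
    "cosine",
    "mean_pool",
    "reverse_reaction",
    "forward_reverse_cosines",
]


@dataclass(frozen=True)
class ReactionEmbedding:
    """A reaction id paired with its dense fingerprint vector."""

    reaction_id: str
    vector: np.ndarray


def _as_smiles(x: Union[Reaction, str]) -> str:
    return x.smiles if isinstance(x, Reaction) else x


class ContrastiveReactionEncoder(BaseEstimator, TransformerMixin):
    """Transformer reaction encoder fine-tuned on similarity-regression pairs.

    Parameters
    ----------
    n_layers, hidden_size, ffn_size, n_heads : int
        Encoder architecture; ``hidden_size`` must be divisible by ``n_heads``.
    pooling : {"mean", "cls"}
        Mean of non-special token embeddings, or the [CLS] position vector.
    max_len : int
        Maximum token-sequence length; longer reactions are truncated with a
        warning.
    max_lr, warmup_fraction, epochs, batch_size : training recipe.
    patience_steps : int
        Early stopping: training stops once this many steps pass without a new
        best validation MSE. Validation is evaluated every ``eval_every`` steps.
    validation_fraction : float
        Fraction of pairs held out for the early-stopping criterion.
    restore_best : bool
        Load the best-validation weights back into the model when fit ends.
    seed : int
        Controls initialization, the train/validation split and shuffling.

    Attributes
    ----------
    model_ : TransformerEncoderModel
    vocab_ : Vocabulary
    loss_history_ : pd.DataFrame with columns (step, train_mse, val_mse)
    n_steps_ : int, optimizer steps actually taken
    best_val_mse_ : float
    """

    def __init__(
        self,
        n_layers: int = 12,
        hidden_size: int = 256,
        ffn_size: int = 512,
        n_heads: int = 4,
        pooling: str = "mean",
        max_len: int = 256,
        max_lr: float = 5e-5,
        warmup_fraction: float = 0.1,
        epochs: int = 5,
        batch_size: int = 32,
        patience_steps: int = 200,
        eval_every: int = 50,
        validation_fraction: float = 0.1,
        restore_best: bool = True,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_size = hidden_size
        self.ffn_size = ffn_size
        self.n_heads = n_heads
        self.pooling = pooling
        self.max_len = max_len
        self.max_lr = max_lr
        self.warmup_fraction = warmup_fraction
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience_steps = patience_steps
        self.eval_every = eval_every
        self.validation_fraction = validation_fraction
        self.restore_best = restore_best
        self.seed = seed

    # -- vocabulary / model initialization -------------------------------

    def initialize(self, smiles_corpus: Sequence[Union[Reaction, str]]) -> "ContrastiveReactionEncoder":
        """Build the vocabulary from a corpus and randomly initialize weights.

        Random initialization stands in for the (out-of-scope) masked-LM
        pre-training stage; a pre-trained parameter dict can be loaded into
        ``model_.params`` afterwards.
        """
        if self.pooling not in ("mean", "cls"):
            raise ValueError(f"pooling must be 'mean' or 'cls', got {self.pooling!r}")
        token_lists = [tokenize_smiles(_as_smiles(s)) for s in smiles_corpus]
        self.vocab_ = Vocabulary.from_corpus(token_lists)
        self.model_ = TransformerEncoderModel(
            vocab_size=len(self.vocab_),
            n_layers=self.n_layers,
            hidden_size=self.hidden_size,
            ffn_size=self.ffn_size,
            n_heads=self.n_heads,
            max_len=self.max_len,
            seed=self.seed,
        )
        self.loss_history_ = pd.DataFrame(columns=["step", "train_mse", "val_mse"])
        self.n_steps_ = 0
        return self

    def _encode_ids(self, smiles: str) -> list[int]:
        tokens = tokenize_smiles(smiles)
        ids = [self.vocab_.cls_id] + self.vocab_.encode(tokens)
        if len(ids) > self.max_len:
            warnings.warn(
                f"reaction of {len(ids)} tokens truncated to max_len={self.max_len}",
                stacklevel=2,
            )
            ids = ids[: self.max_len]
        return ids

    def _batch(self, id_lists: Sequence[list[int]]):
        """Pad a list of id sequences into (ids, attn_mask, pool_mask)."""
        T = max(len(ids) for ids in id_lists)
        B = len(id_lists)
        pad = self.vocab_.pad_id
        ids = np.full((B, T), pad, dtype=np.intp)
        attn = np.zeros((B, T))
        for i, seq in enumerate(id_lists):
            ids[i, : len(seq)] = seq
            attn[i, : len(seq)] = 1.0
        pool = attn.copy()
        pool[:, 0] = 0.0  # [CLS] excluded from the mean pool
        return ids, attn, pool

    def _pool(self, hidden: np.ndarray, pool_mask: np.ndarray) -> np.ndarray:
        if self.pooling == "cls":
            return hidden[:, 0, :]
        return mean_pool(hidden, pool_mask)

    def _pool_backward(self, d_pooled: np.ndarray, hidden_shape, pool_mask: np.ndarray) -> np.ndarray:
        d_hidden = np.zeros(hidden_shape)
        if self.pooling == "cls":
            d_hidden[:, 0, :] = d_pooled
        else:
            counts = pool_mask.sum(axis=1)
            d_hidden += pool_mask[:, :, None] * d_pooled[:, None, :] / counts[:, None, None]
        return d_hidden

    # -- training --------------------------------------------------------

    @staticmethod
    def _pairs_frame(pairs) -> pd.DataFrame:
        if isinstance(pairs, pd.DataFrame):
            df = pairs
        elif len(pairs) and isinstance(pairs[0], ReactionPair):
            df = pairs_to_frame(pairs)
        else:
            raise TypeError("pairs must be a DataFrame or a sequence of ReactionPair")
        for col in ("smiles_a", "smiles_b", "target"):
            if col not in df.columns:
                raise ValueError(f"pair data missing column {col!r}")
        return df

    def fit(self, pairs, y=None) -> "ContrastiveReactionEncoder":
        """Contrastively fine-tune on (smiles_a, smiles_b, target) pairs."""
        df = self._pairs_frame(pairs)
        if len(df) == 0:
            raise ValueError("empty training set")
        if not hasattr(self, "model_"):
            self.initialize(list(df["smiles_a"]) + list(df["smiles_b"]))

        ids_a = [self._encode_ids(s) for s in df["smiles_a"]]
        ids_b = [self._encode_ids(s) for s in df["smiles_b"]]
        targets = df["target"].to_numpy(dtype=float)

        rng = np.random.default_rng(self.seed + 1)
        order = rng.permutation(len(df))
        n_val = max(int(round(self.validation_fraction * len(df))), 1) if len(df) > 1 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = order, order[:0]

        steps_per_epoch = max(int(np.ceil(len(train_idx) / self.batch_size)), 1)
        total_steps = steps_per_epoch * self.epochs
        history: list[dict] = []
        if self.epochs <= 0 or total_steps == 0:
            self.n_steps_ = 0
            self.best_val_mse_ = float("nan")
            self.loss_history_ = pd.DataFrame(history, columns=["step", "train_mse", "val_mse"])
            return self

        schedule = WarmupLinearSchedule(self.max_lr, total_steps, self.warmup_fraction)
        optimizer = AdamOptimizer(self.model_.params)

        def val_mse() -> float:
            if len(val_idx) == 0:
                return float("nan")
            preds, tgts = [], []
            for start in range(0, len(val_idx), self.batch_size):
                chunk = val_idx[start : start + self.batch_size]
                u = self._forward_pooled([ids_a[i] for i in chunk])
                v = self._forward_pooled([ids_b[i] for i in chunk])
                dots = (u * v).sum(axis=1)
                c = dots / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
                preds.append(c)
                tgts.append(targets[chunk])
            resid = np.concatenate(preds) - np.concatenate(tgts)
            return float(np.mean(resid**2))

        best_val = val_mse()
        best_params = self.model_.copy_params() if self.restore_best else None
        best_step = 0
        step = 0
        stop = False
        history.append({"step": 0, "train_mse": np.nan, "val_mse": best_val})

        for _epoch in range(self.epochs):
            epoch_order = rng.permutation(train_idx)
            for start in range(0, len(epoch_order), self.batch_size):
                chunk = epoch_order[start : start + self.batch_size]
                step += 1
                batch_a = self._batch([ids_a[i] for i in chunk])
                batch_b = self._batch([ids_b[i] for i in chunk])
                ha, ca = self.model_.forward(batch_a[0], batch_a[1])
                hb, cb = self.model_.forward(batch_b[0], batch_b[1])
                u = self._pool(ha, batch_a[2])
                v = self._pool(hb, batch_b[2])
                loss, _, du, dv = cosine_mse_loss(u, v, targets[chunk])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss {loss} at step {step}; "
                        "check inputs and learning rate"
                    )
                ga = self.model_.backward(ca, self._pool_backward(du, ha.shape, batch_a[2]))
                gb = self.model_.backward(cb, self._pool_backward(dv, hb.shape, batch_b[2]))
                grads = {k: ga[k] + gb[k] for k in ga}
                optimizer.step(self.model_.params, grads, schedule.lr(step))

                record = {"step": step, "train_mse": loss, "val_mse": np.nan}
                if len(val_idx) and step % self.eval_every == 0:
                    vm = val_mse()
                    record["val_mse"] = vm
                    if vm < best_val:
                        best_val = vm
                        best_step = step
                        if self.restore_best:
                            best_params = self.model_.copy_params()
                    elif step - best_step >= self.patience_steps:
                        stop = True
                history.append(record)
                if stop:
                    break
            if stop:
                break

        if self.restore_best and best_params is not None and len(val_idx):
            final = val_mse()
            if best_val < final:
                self.model_.load_params(best_params)
        self.n_steps_ = step
        self.best_val_mse_ = best_val
        self.loss_history_ = pd.DataFrame(history, columns=["step", "train_mse", "val_mse"])
        return self

    # -- inference -------------------------------------------------------

    def _forward_pooled(self, id_lists: Sequence[list[int]]) -> np.ndarray:
        ids, attn, pool = self._batch(id_lists)
        hidden, _ = self.model_.forward(ids, attn, need_cache=False)
        return self._pool(hidden, pool)

    def transform(self, X: Sequence[Union[Reaction, str]]) -> np.ndarray:
        """Embed reactions into (n, hidden_size) fingerprint vectors."""
        self._check_initialized()
        out = []
        for start in range(0, len(X), self.batch_size):
            chunk = [self._encode_ids(_as_smiles(x)) for x in X[start : start + self.batch_size]]
            out.append(self._forward_pooled(chunk))
        return np.concatenate(out, axis=0)

    def encode(self, reactions: Sequence[Reaction]) -> list[ReactionEmbedding]:
        """Embeddings tagged with reaction ids."""
        vectors = self.transform(reactions)
        return [
            ReactionEmbedding(reaction_id=r.id, vector=v)
            for r, v in zip(reactions, vectors)
        ]

    def attention_map(
        self, reaction: Union[Reaction, str], renormalize: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Layer-by-token attention summary (n_layers, n_tokens).

        Mean pooling: attention to each token averaged over heads and over all
        query positions; [CLS] pooling: averaged over heads with the query
        fixed at the [CLS] position. Rows are renormalized to sum to 1 by
        default. Returns the map together with the token strings (position 0 is
        [CLS]).
        """
        self._check_initialized()
        ids = self._encode_ids(_as_smiles(reaction))
        batch_ids, attn, _ = self._batch([ids])
        _, cache = self.model_.forward(batch_ids, attn)
        rows = []
        for att in cache["attn"]:  # (1, heads, T, T)
            per_head = att[0].mean(axis=0)  # (T, T): query x key
            row = per_head[0] if self.pooling == "cls" else per_head.mean(axis=0)
            rows.append(row)
        amap = np.stack(rows)
        if renormalize:
            amap = amap / amap.sum(axis=1, keepdims=True)
        tokens = [CLS_TOKEN] + tokenize_smiles(_as_smiles(reaction))[: len(ids) - 1]
        return amap, tokens

    def _check_initialized(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError(
                "encoder is not initialized; call initialize(corpus) or fit(pairs) first"
            )


def forward_reverse_cosines(
    encoder: ContrastiveReactionEncoder, reactions: Sequence[Reaction]
) -> np.ndarray:
    """Cosine similarity between each reaction and its reversed counterpart.

    The distribution of these values is the directionality diagnostic: values
    near 1 mean the encoder ignores reaction direction, low values mean
    forward and reverse reactions embed differently.
    """
    fwd = encoder.transform(reactions)
    rev = encoder.transform([reverse_reaction(r) for r in reactions])
    return np.array([cosine(a, b) for a, b in zip(fwd, rev)])
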