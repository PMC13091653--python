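"""Shared fixtures: synthetic corpora and a desk-scale trained encoder.

The expensive pieces (corpus generation, contrastive training) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from crxnfp.encoder import ContrastiveReactionEncoder
from crxnfp.pairs import BinScheme, pairs_to_frame, sample_pairs
from crxnfp.synthetic import make_labeled_corpus

CORPUS_SEED = 7
# Desk-scale encoder: 2 transformer layers, hidden 64. Random init stands in
# for masked-LM pre-training, so the fine-tuning LR is larger than the
# full-scale 5e-5 recipe.
DESK_ENCODER = dict(n_layers=2, hidden_size=64, ffn_size=128, n_heads=4)
DESK_TRAINING = dict(epochs=3, batch_size=32, max_lr=5e-4, eval_every=20, patience_steps=200)


@pytest.fixture(scope="session")
def corpus():
    """Template-labeled synthetic corpus: 6 templates x 30 reactions."""
    return make_labeled_corpus(n_per_class=30, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def small_corpus(corpus):
    """A light subset for parsing/fingerprint property tests."""
    return corpus[::3]


@pytest.fixture(scope="session")
def pair_data(corpus):
    """~2500 stratified contrastive pairs split into train and held-out eval."""
    scheme = BinScheme(quotas=(250,) * 6 + (1000,))
    pairs = sample_pairs(corpus, scheme, seed=CORPUS_SEED)
    df = pairs_to_frame(pairs)
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(df))
    return {
        "pairs": pairs,
        "train": df.iloc[idx[300:]].reset_index(drop=True),
        "test": df.iloc[idx[:300]].reset_index(drop=True),
    }


@pytest.fixture(scope="session")
def untrained_encoder(corpus):
    enc = ContrastiveReactionEncoder(**DESK_ENCODER, seed=3)
    enc.initialize([r.smiles for r in corpus])
    return enc


@pytest.fixture(scope="session")
def trained_encoder(corpus, pair_data):
    enc = ContrastiveReactionEncoder(**DESK_ENCODER, **DESK_TRAINING, seed=3)
    enc.initialize([r.smiles for r in corpus])
    enc.fit(pair_data["train"])
    return enc
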