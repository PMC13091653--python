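# crxnfp

Compact, contrastively trained reaction fingerprints for chemical-reaction
classification and similarity-based enzyme association.

## The problem

Environmental biotransformation of contaminants is driven by microbial
enzymes, but most reactions in biotransformation databases have no enzyme
annotation. A practical route to annotation is similarity search: embed a
query reaction, find the most similar enzyme-annotated reference reactions
(e.g. Rhea entries cross-linked to UniProt), and transfer their EC numbers.
That only works if the embedding clusters reactions by *transformation type*
— which generic SMILES language models often fail to do without fine-tuning.

This package learns such embeddings with a self-supervised, contrastive
objective that needs no atom mapping and no labels. A BERT-style transformer
encoder reads the reaction SMILES `reactants>>products`, its token embeddings
are mean-pooled into one vector per reaction, and the encoder is fine-tuned so
that the cosine similarity of two reaction embeddings regresses onto a
structural similarity signal computed directly from the molecules:

- the **differential reaction fingerprint (drfp)**: the symmetric difference
  between the circular-substructure sets of the reactant and product sides,
  hashed into 2048 bits — unchanged substructures cancel, so the surviving
  bits describe the reaction center;
- the **Tanimoto similarity** `T = |A∩B| / |A∪B|` of two such fingerprints,
  exponentially rescaled to spread the low-similarity mass:

  `target = 1 − exp(−5·T)`  (0 ↦ 0, 1 ↦ 1 − e⁻⁵ ≈ 0.9933);

- a training set of reaction pairs stratified into seven bins of the
  transformed score (0–0.1, …, 0.5–0.6, and a wide 0.6–1.0 bin with a 4×
  quota, since highly similar pairs are rare), trained with an MSE loss
  between embedding cosine and target.

On top of the embeddings the package provides cosine-KNN and MLP reaction
classifiers with accuracy / MCC / CEN metrics, and an enzyme-association
workflow: top-k cosine neighbors above a threshold (default k = 5,
cosine > 0.5), EC prediction from the neighbors, and hierarchical EC scoring
(level-k accuracy compares the first k fields of the EC number, honoring
truncated references such as `6.2.1` and composite references such as
`3.8.1.3 AND 3.8.1.2`). Queries with no neighbor above the threshold get an
explicit `no_analogous_reaction` status rather than a forced guess.

The transformer encoder, its exact-gradient training loop, the fingerprints
and the samplers are implemented in NumPy/RDKit inside this package; standard
steps (MLP classifier, table I/O, statistics) use scikit-learn, pandas and
SciPy.

## Worked example

Score the packaged 23-reaction fluorinated-compound benchmark (reference EC
classes plus the printed predictions of three tools):

```bash
$ crxnfp score-ec --column crxnfp --level 3
crxnfp level-3 accuracy: 91.30%
$ crxnfp score-ec --column theia --level 2
theia level-2 accuracy: 34.78%
```

21 of the 23 reactions are predicted correctly by the similarity-based method
through EC level 3; the two misses are amide hydrolyses with no sufficiently
similar reference reaction (cosine ≤ 0.5), which count as errors.

A desk-scale end-to-end run on synthetic data (6 transformation templates ×
30 reactions, 2500 stratified pairs, a 2-layer/hidden-64 encoder):

```bash
$ crxnfp synth --out-dir fixtures --n 30 --seed 7
$ crxnfp pairs --in fixtures/reactions.tsv --quota 250 --seed 7 --out pairs.tsv
$ crxnfp train --pairs pairs.tsv --out-dir model --layers 2 --hidden 64 \
      --ffn 128 --heads 2 --lr 5e-4 --epochs 3 --seed 3
$ crxnfp fingerprint --model model --in fixtures/reactions.tsv --out emb.tsv
```

In a run of this pipeline the held-out pair MSE dropped from 0.149 (random
encoder) to 0.044 after fine-tuning, the Spearman correlation between
embedding cosine and drfp Tanimoto rose from 0.36 to 0.78, and 3-NN
template-classification accuracy on a held-out corpus rose from 0.65 to 0.95
— training aligns the embedding space with the structural transformation,
which is exactly what the similarity-based enzyme association relies on.

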