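# pbip — strain-level phage–bacterium interaction prediction

Phage therapy needs to know, for a concrete bacterial isolate, which phages
will infect it. `pbip` is a library and command-line tool for predicting such
phage–bacterium interactions (PBIs) at the strain level from protein
sequences alone, built for researchers who have per-organism proteomes and a
partially observed infection matrix (e.g. from double-layer agar plaque
assays).

## The method

A pair (phage *P*, bacterium *B*) is a binary classification instance
(*y* = 1: productive infection). The pipeline:

1. **Protein embedding.** Each protein *S* = (*a*₁ … *a*_T) over the 20
   standard amino acids is one-hot encoded (*X*_one = OneHot(*S*)), projected
   through a learned token embedding (*X*_emb = *X*_one *W*_emb), and run
   through a multiplicative LSTM; the protein vector is the time-average
   *x* = (1/*T*) Σₜ *h*ₜ. Organism vectors average over proteins,
   *x*_p = (1/*N*_p) Σᵢ *x*_pᵢ, and a pair is the concatenation [*x*_p, *x*_b].
   The canonical pretrained 1900-unit weights can be loaded from disk;
   seeded random weights (any *d*_h) support desk-scale work.
2. **Class balancing.** Positive interactions are rare (7.22% in the
   motivating strain-level screen), so the minority class is oversampled by
   SMOTE in the embedding space:
   [*x*_p, *x*_b]′ = [*x*_p, *x*_b] + α·([*x*_p, *x*_b]_n − [*x*_p, *x*_b]),
   α ~ U[0,1], until the training classes are equal. Synthetic samples carry
   full provenance (parent indices, α). Test sets are never augmented.
3. **Classifier.** Per organism: four 1-D convolution stages
   (*x*ᶜₜ = ReLU(*W*ᶜ ∗ *x*ᵢ + *b*ᶜ), kernel 3, max-pool 2, filters
   [32, 64, 128, 256]) → bidirectional GRU (hidden 64, per-step concatenation
   of directions) → additive attention pooling *h*ᴬ = Σₜ αᴬₜ *h*ᴳₜ with
   Σ αᴬₜ = 1. The pooled phage and bacterium vectors are concatenated into a
   fully connected sigmoid layer, ŷ = σ(*W*_f(*h*ᴬ_p ⊕ *h*ᴬ_b) + *b*_f).
   Training minimizes mean binary cross-entropy with AMSGrad (lr 3e-4,
   batch 16, 200 epochs at full scale). The network, its backward pass and
   the optimizer are implemented in plain numpy.
4. **Evaluation.** Accuracy, precision, sensitivity, specificity, F1, MCC,
   AUC and AUPR; stratified 10-fold cross-validation with augmentation inside
   each training split only; nine imbalanced test sets at positive:negative
   ratios 1:2 … 1:10 (MCC is the headline metric there); MinHash k-mer
   similarity auditing of train/test phage overlap and a leakage filter for
   training negatives.

A synthetic-data module generates desk-scale proteomes with a planted
phage-motif × bacterium-motif compatibility rule, so the whole pipeline is
exercisable and testable without any download.

## Worked example

`python examples/04_train_and_evaluate.py` simulates a 40×40 planted-motif
matrix, embeds it (*d*_h = 16), balances the training split and trains the
reduced classifier for 30 epochs:

```
simulated 40x40 matrix, 28.9% positive
training pairs 1200 -> 1708 after SMOTE
training loss 0.694 -> 0.329 over 30 epochs
  accuracy     0.895
  precision    0.734
  sensitivity  1.000
  specificity  0.852
  f1           0.847
  mcc          0.791
  auc          0.978
  aupr         0.935
```

The held-out AUC of 0.978 shows the model recovered the planted motif
compatibility rule from sequence alone; a label-shuffled control sits at
AUC ≈ 0.5. The other examples cover dataset statistics (`01`), embeddings
(`02`), SMOTE provenance (`03`) and similarity auditing (`05`).

The same pipeline is available from the shell:

```bash
pbip simulate --profile desk --seed 1 --out runs/data
pbip run --profile desk --seed 1 --out runs/full
pbip stats --interactions runs/data/interactions.csv
```

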