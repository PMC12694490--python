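# Methods

This note documents the models, conventions and design choices behind
`pbip`, in the order data flows through the pipeline.

## Problem setting and data model

A strain-level interaction screen yields a (near-)complete phage × bacterium
matrix of binary outcomes. Labels may arrive directly or as replicate plaque
scores: the consensus rule marks a pair positive when at least 2 replicates
score strictly above 1.5 (a score exactly at the threshold is negative; the
composite score itself is produced upstream by plaque-image analysis and is
out of scope here). The rule accepts any replicate count ≥ 1. Matrix
statistics and the fully-resistant-strain filter require a complete matrix;
training-mode tables may be partial, so records are keyed by explicit ids,
never positional indices.

Sequences are restricted to the 20 canonical amino acids in the fixed order
`ARNDCEQGHILKMFPSTWYV` (index 0 = A). Non-standard codes (X, B, Z, U, J, O,
\*) are dropped position-wise under the default policy or rejected under the
strict one; a record left empty by dropping is an error.

## Protein embedding (mLSTM)

The embedder follows the UniRep-style multiplicative-LSTM protein language
model. For token embeddings *X*ₜ (dimension *d*_e, default 10) and hidden
size *d*_h (canonical 1900):

    m_t  = (W_mx X_t) ⊙ (W_mh h_{t−1})
    i_t  = σ(W_ix X_t + W_im m_t + b_i)      (forget f, output o likewise)
    c̃_t = tanh(W_cx X_t + W_cm m_t + b_c)
    c_t  = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t
    h_t  = o_t ⊙ tanh(c_t)

with zero initial hidden and cell states, no length cap or truncation, and
gate blocks stacked in order (i, f, o, candidate). The protein embedding is
the time-average of hidden states; organisms average over proteins (order
invariant); a pair is the concatenation [x_p, x_b] of length 2·d_h.

Pretrained arrays are loaded from a directory of `.npy` files
(`embed_matrix`, `wx`, `wh`, `wmx`, `wmh`, `b`) with shapes validated
against the declared (d_e, d_h). When no weights are supplied, parameters
are drawn from a seeded Gaussian scaled by 1/√fan_in with zero biases —
this is not a trained model but a random features extractor; it preserves
enough sequence information at small d_h for the synthetic studies below.

## SMOTE in the embedding space

Minority (positive) pairs are oversampled until the classes are equal:
pick a random positive seed (with replacement), one of its k = 5 nearest
positive neighbors (Euclidean distance on the whole 2·d_h pair vector), and
an independent α ~ U[0,1], all from one seeded generator. Interpolation acts
on the joint pair vector, not per-organism halves. Every synthetic sample
records its two parents and α, so tests can verify the collinearity residual
is ~0. Originals are preserved unmodified and first in the output;
augmentation is only ever applied to training splits (cross-validation
augments inside each fold's training part). k must be smaller than the
positive count; the error message suggests lowering it. The no-augmentation
ablation replaces this stage with a pass-through.

## Classifier

Each organism embedding is treated as a 1-channel, length-d_h 1-D signal.
Per tower: `conv_layers` stages of (convolution kernel 3, same padding →
ReLU → non-overlapping max-pool 2, remainder dropped), filters
[32, 64, 128, 256] at full scale; dropout once after the tower. With same
padding only pooling shrinks the signal: 1900 → 950 → 475 → 237 → 118.
Then a bidirectional GRU (hidden 64; standard reset/update/candidate gates;
per-step concatenation of the two directions) with dropout on its output,
and additive attention

    score_t = vᵀ tanh(W h_t + b),   α = softmax(score),   h^A = Σ α_t h_t

with 32 attention units. The phage and bacterium towers are separate
(untied) by default — the safer superset; `tower_sharing="shared"` ties
them. The pooled vectors are concatenated into one fully connected sigmoid
unit. Note the two towers meet only in that final affine layer, so the
decision logit is additive in per-organism features; this matters for what
interaction rules the model can express (see the generator below).

Training: mean binary cross-entropy with predictions clipped to
[1e-7, 1 − 1e-7]; AMSGrad (Adam with a non-decreasing second-moment
estimate, β₁ = 0.9, β₂ = 0.999, ε = 1e-8); mini-batches reshuffled each
epoch from the run seed, last incomplete batch kept; dropout active in
training only; Glorot-uniform seeded initialization, zero biases.
Classification threshold 0.5, ties toward positive. Forward, backward and
the optimizer are hand-written numpy; backpropagation is verified against
central finite differences in the test suite (median relative error < 1e-6;
isolated ReLU/max-pool kinks excluded by a median/max two-level assertion).

Ablation switches mirror the framework variants: `PBIP3` removes the Bi-GRU
(attention pools CNN features directly), `PBIP4` removes attention
(mean-pooling of GRU states), `PBIP5` disables SMOTE.

### Reduced desk-scale configuration

`ModelConfig.reduced()`: filters [8, 16], GRU hidden 8, 16 attention units,
dropout 0.25, for inputs of d_h ≈ 16. `TrainConfig.reduced()`: 30 epochs at
learning rate 3e-3. The full-scale rate of 3e-4 is tuned for 200-epoch runs
and underfits badly within 30 epochs at this scale (training loss stalls
near ln 2 ≈ 0.693); 3e-3 was chosen from that optimization diagnostic. The
smaller dropout reflects the much smaller parameter count.

## Evaluation

Eight metrics from the standard confusion-count formulas. Degenerate
conventions: precision = 0 when TP+FP = 0; MCC = 0 when any denominator
factor is 0; F1 = 0 when precision + recall = 0. AUC is computed so that it
equals the Mann–Whitney probability (ties ½); AUPR is the step-wise,
non-interpolated area (linear PR interpolation is optimistic). ROC/PR
machinery is delegated to scikit-learn; tests hold both against O(n²)
brute-force oracles at 1e-12.

Cross-validation is stratified by label (k = 10), folds disjoint and
exhaustive, augmentation inside training splits only, mean ± sd per metric.
The imbalance case study builds nine test sets at ratios 1:2 … 1:10 — all
positives plus ratio × |positives| negatives sampled without replacement —
with MCC as the designated comparison metric; out-of-protocol ratios
require an explicit override.

Similarity auditing uses a bottom-k MinHash estimate of k-mer Jaccard
similarity (k = 21, sketch 1024, keyed blake2b hashing, deterministic and
symmetric; exact when the k-mer sets fit in the sketch). This is a
documented stand-in for HyperLogLog-sketching tools used in the original
protocol; absolute values are a different similarity scale, so only
relative comparisons and binning should be read from it. Test phages are
binned by their maximum similarity to training phages into five equal-width
intervals over [0,1] (upper-edge values fall in the higher bin; empty bins
report count 0 and undefined accuracy). The leakage filter removes training
negatives whose phage reaches similarity ≥ 0.9 (configurable; the notion of
"substantial overlap" is not quantified upstream) to any test phage, and
returns a removal log.

## Synthetic data generator

The generator emulates the structure of a strain-level screen: 20–120
organisms per role, several proteins each, i.i.d. background residues
(default uniform; composition effects can be switched on via
`background_frequencies`). Each organism gets a hidden motif class; the
class motif (a fixed random string, default length 8) is spliced into one
randomly chosen protein at a random position. Labels are a lookup in a
binary class-compatibility matrix, then flipped with probability
`noise_rate` (symmetric label noise; default 0 — consensus labels from the
assay are treated as clean).

The default compatibility is a *nested* host-range rule: positive iff
phage class + bacterium class ≥ 2(c−1) (for two classes: infective phage AND
susceptible bacterium). Two reasons. Biologically, real phage–bacteria
infection matrices are strongly nested. Architecturally, the classifier's
towers combine additively in the final layer, so an XOR-like rule such as
the identity matrix (positive iff same class) is not expressible by the
model regardless of training; a nested rule is additively separable.
Arbitrary matrices (including identity) remain configurable and are used in
generator-level counting tests.

Profiles: `unit` (6×6, 2 proteins of 30–60 aa — fast tests), `desk` (40×40,
3–6 proteins of 80–200 aa, 2 classes at P = 0.5 → 25% positive rate), and
`paper-shape` (104×120 = 12 480 records, class priors 0.269 → expected
positive rate 7.23%, matching the sparsity of the motivating screen).
`strain_matrix_like` separately reconstructs a label-only matrix with the
published summary counts (13 000 pairs, 938 positives, 5 fully resistant
strains) for dataset arithmetic; it is synthetic and carries no sequences.

### What passing tests do and do not show

The generator plants a clean, localized, literally repeated motif in i.i.d.
background — far easier than real proteomes, where host range is governed by
receptor-binding protein variation, shared core genomes, phylogenetic
correlation between organisms, and assay noise. Desk-scale results
(held-out AUC ≈ 0.93–0.98 at the three study seeds; ≈ 0.89 on average with a
0.72–1.00 range over a wider seed scan, the weak tail being runs that have
not converged within the fixed 30-epoch budget) therefore demonstrate that
the implementation can propagate and learn a sequence-borne interaction
signal end to end — not that comparable accuracy transfers to real
strain-level data, which additionally requires the pretrained 1900-unit
embedder. The label-shuffled control (AUC ≈ 0.5) rules out leakage through
the generator or pipeline.

## Determinism and problem sizes

One global seed fans out to per-stage sub-seeds via a CRC of the stage name
(kept below 2³¹), so stages are independently re-runnable and a repeated run
reproduces its metrics exactly on the same machine. The test suite and the
acceptance script run at desk scale — d_h = 16 embeddings, 40×40 matrices,
30-epoch training, ~1 000-instance metric oracles — sizes chosen so the full
pipeline, including three learnability seeds and a shuffled control,
completes in about a minute on one CPU while still exercising every stage.

## Known limitations

- Random embedder weights are a random-features stand-in; biological
  fidelity of embeddings requires the released pretrained arrays.
- The additive tower combination bounds the class of learnable interaction
  rules (no strict phage×bacterium epistasis); this is inherent to the PBIP
  architecture rather than a choice made here.
- MinHash similarity is not numerically comparable to HyperLogLog-based
  similarity scores; only orderings and bins are meaningful.
- The plaque composite score is consumed, never computed; replicate counts
  other than three are accepted but untested against real assay practice.
- Training is fixed-epoch (no early stopping, no validation checkpointing),
  as in the PBIP training protocol; at desk scale a minority of seeds
  under-converge within 30 epochs.
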