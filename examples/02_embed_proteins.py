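"""Protein -> organism -> pair embeddings with a seeded mLSTM.

Builds two tiny proteomes, runs the one-hot -> token-embedding -> mLSTM ->
time-average chain on each protein, averages per organism and concatenates
the phage and bacterium vectors into the pair representation the classifier
consumes.  Random seeded weights stand in for the released pretrained arrays
(drop them in a directory and use load_pretrained_weights for the 1900-unit
model).
"""

import numpy as np

from pbip import ProteinSequence, OrganismProteome, embed_pair, protein_embedding, random_params

params = random_params(d_e=10, d_h=16, seed=0)

phage = OrganismProteome(
    id="phageA",
    role="phage",
    proteins=(
        ProteinSequence("rbp", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        ProteinSequence("capsid", "MSTNPKPQRKTKRNTNRRPQDVKFPGG"),
    ),
)
bacterium = OrganismProteome(
    id="strain7",
    role="bacterium",
    proteins=(
        ProteinSequence("ompA", "MKKTAIAIAVALAGFATVAQAAPKDNTWYTGAKLGWSQYHDTGFINNNGPTHENQLGAGAFGGYQVNPYVGFEMGYDWLGRMPYKGSVENGAYKAQGVQLTAKLGYPITDDLDIYTRLGGMVWRADTKSNVYGKNHDTGVSPVFAGGVEYAITPEIATRLEYQWTNNIGDAHTIGTRPDNGMLSLGVSYRFG"),
    ),
)

emb = protein_embedding(phage.proteins[0], params)
print(f"protein {emb.source_id!r}: d_h={emb.vector.shape[0]}, "
      f"first 4 components {np.round(emb.vector[:4], 4)}")

pair = embed_pair(phage, bacterium, params)
print(f"pair [{pair.phage_id}, {pair.bacterium_id}]: vector length {pair.vector.shape[0]}")
print(f"  phage half mean {pair.x_p.mean():+.4f}, bacterium half mean {pair.x_b.mean():+.4f}")

# The pair vector [x_p, x_b] (length 2*d_h) is the unit of downstream work:
# SMOTE interpolates it, the classifier splits it back into its two halves.
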