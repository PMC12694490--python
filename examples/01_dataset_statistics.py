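"""Interaction-matrix bookkeeping: summary statistics and strain filtering.

Reconstructs a complete strain-level interaction matrix with the published
summary counts (104 phages x 125 bacterial strains, 938 positives, 5 fully
resistant strains), prints its statistics, and removes the fully resistant
strains the way the training dataset was cleaned.
"""

from pbip import drop_fully_resistant_strains, matrix_statistics, strain_matrix_like

table = strain_matrix_like(n_phages=104, n_bacteria=125, n_positive=938,
                           n_fully_resistant=5)
stats = matrix_statistics(table)
print("complete matrix:")
for key, value in stats.items():
    print(f"  {key}: {value}")

filtered = drop_fully_resistant_strains(table)
print("\nafter dropping fully resistant strains:")
print(f"  remaining strains: {len(filtered.bacterium_ids)}")
print(f"  valid records:     {len(filtered)}")

# The positive fraction (7.22%) is the class imbalance the SMOTE stage has to
# correct; the per-phage mean (~9 susceptible strains) reflects narrow host
# ranges typical of strain-level interaction screens.
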