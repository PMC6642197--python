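"""Simulate a three-species digit dataset and normalize it for clustering.

Generates NB counts for mouse/alligator/anolis forelimbs (5 digits x 3
replicates each) with a planted 30-gene conserved D1 module, then converts
the mouse counts to TPM, square-root transforms them and mean-centers.
"""

import numpy as np

from digitexpr import conserved_module_config, simulate_counts
from digitexpr import bulk_center, sqrt_transform, tpm_matrix

res = simulate_counts(conserved_module_config(seed=1))
cm = res.counts["mouse"]
print(f"mouse counts: {cm.n_genes} genes x {cm.n_samples} samples")
print(f"one-to-one ortholog groups across species: {res.orthologs.n_one_to_one}")

em = tpm_matrix(cm, res.lengths)
print(f"TPM column sums (should all be 1e6): {np.round(em.values.sum(axis=0).unique(), 3)}")

sq = sqrt_transform(em)
centered = bulk_center(sq, {s: "fore" for s in sq.sample_ids})
gene_means = centered.values.mean(axis=1)
print(f"max |per-gene mean| after centering: {np.abs(gene_means).max():.2e}")
# The planted D1 module is 4-fold up in digit 1: compare mean TPM there
d1 = [s for s in cm.sample_ids if cm.metadata.loc[s, "digit"] == 1]
d2 = [s for s in cm.sample_ids if cm.metadata.loc[s, "digit"] == 2]
mod = sorted(res.truth.modules_by_species_gene[("mouse", "D1_module")])
ratio = em.values.loc[mod, d1].mean().mean() / em.values.loc[mod, d2].mean().mean()
print(f"module TPM ratio D1/D2 ~= 4: {ratio:.2f}")
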