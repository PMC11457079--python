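"""Admixture analysis with cross-validated K, PCA, and group assignment.

The cross-validation table should dip at the true number of populations
(3 here); samples are then assigned to an admixture group when their
maximum ancestry fraction reaches 0.7.
"""

import pandas as pd

from riverpop import (
    PopulationModel,
    assign_groups,
    fit_admixture,
    genotype_pca,
    prune_ld,
    select_k,
    simulate_haplotypes,
    truth_genotype_matrix,
)

pm = PopulationModel(n_pops=3, samples_per_pop=20, n_sites=3000,
                     chrom_length=30_000_000, fst=0.10, seed=2)
truth = simulate_haplotypes(pm)
pruned = prune_ld(truth_genotype_matrix(truth))

best_k, cv = select_k(pruned, range(1, 6), seed=2)
print(cv.to_string(index=False))
print(f"\nlowest CV error at K = {best_k}")

fit = fit_admixture(pruned, best_k, seed=2)
meta = pd.DataFrame({"sample": pruned.samples,
                     "location": [f"loc{p}" for p in truth.pop_labels]})
assignments = assign_groups(fit.Q, meta, threshold=0.7, level="sample")
print("\nassignment counts:")
print(assignments["group"].value_counts().to_string())

pca = genotype_pca(pruned, n_components=2)
print(f"\nPC1 explains {pca.explained_variance_ratio[0]:.1%}, "
      f"PC2 {pca.explained_variance_ratio[1]:.1%} of genotype variance")
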