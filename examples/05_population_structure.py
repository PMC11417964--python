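"""Population structure: PCA outliers, admixture fractions, NJ tree.

Two strongly diverged populations: the masked-CV factorization should pick
K = 2 with clean ancestry, the PCA scan flags the most differentiated SNPs,
and the neighbor-joining tree of allele-sharing distances separates the
groups.
"""

import numpy as np
import pandas as pd

from consgen import structure, syndata

anc, freqs = syndata.simulate_frequencies(600, 2, 0.4, seed=5)
table, pop_map = syndata.simulate_genotypes(freqs, [8, 8], seed=6)

pca, pca_hits = structure.pca_and_outliers(table, K=2, fdr=0.01)
print(f"PC1+PC2 explain {100 * pca.explained_variance[:2].sum():.1f}% "
      f"of the genotype covariance; {len(pca_hits)} PCA outlier SNPs")

adm = structure.admixture_factorization(table, K_range=[1, 2, 3], seed=0)
print(f"cross-validation selects K = {adm.K}; "
      f"cv errors: { {k: round(v, 4) for k, v in adm.cv_error.items()} }")
print("mean max ancestry fraction:", round(adm.Q.max(axis=1).mean(), 3))

fact_hits = structure.factorization_outliers(table, adm, fdr=0.01)
part = structure.partition_loci(pca_hits, fact_hits,
                                set(range(table.n_sites)))
print(f"adaptive loci (both scans): {len(part.adaptive)}; "
      f"neutral: {len(part.neutral)}")

D = structure.allele_sharing_distance(table)
print("\nNJ tree of 1-IBS distances (first 4 samples per pop shown):")
sub = list(table.samples[:4]) + list(table.samples[8:12])
print(structure.neighbor_joining(D.loc[sub, sub]))
# Q rows near 0/1 mean unadmixed samples; the adaptive set is the
# intersection of the two outlier scans, everything else is called neutral.
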