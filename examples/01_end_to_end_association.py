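"""End-to-end cWAS on a synthetic study.

Builds a small LD-structured cohort, plants a phenotype driven by one cell
type's genetically regulated proportion (GRP), runs a per-SNP GWAS, and then
recovers the causal cell type from the summary statistics alone.
"""

import numpy as np

from cwas import (AssocConfig, PhenotypeModel, associations_frame, run_cwas,
                  run_gwas, simulate_genotypes, simulate_phenotype,
                  simulate_weights_and_signature)
from cwas.grp_engine import deconvolve, impute_expression, transform_weights

rng = np.random.default_rng(1)

# reference cohort: 2,000 individuals x 600 SNPs, AR-1 LD 0.3
panel = simulate_genotypes(2000, 600, ld=0.3, rng=rng)
weights, signature = simulate_weights_and_signature(panel, n_genes=60,
                                                    n_celltypes=6, rng=rng)

# genetically regulated proportions on the cohort
tw = transform_weights(weights, signature)
grp = deconvolve(impute_expression(panel, weights), tw, signature)

# phenotype: CT3's GRP explains 5% of trait variance
model = PhenotypeModel(cell_type=2, h2=0.05)
y = simulate_phenotype(grp, model, rng)
gwas = run_gwas(panel, y)

results, _ = run_cwas(gwas, weights, signature, panel,
                      AssocConfig(min_signature_genes=10))
print(associations_frame(results).to_string(index=False))
print(f"\nplanted effect: cell type CT3, gamma = {model.gamma:+.3f}")
print("A |z| of ~10 with p_bonf << 0.05 on CT3 means the summary-statistic "
      "test recovered the planted cell type and its direction. Cell types "
      "whose GRPs correlate with CT3's can reach moderate |z| too — the "
      "known dependency cost of correlated proportions — but the causal one "
      "dominates by a wide margin.")
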