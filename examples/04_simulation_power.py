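"""A miniature replicated power and type-I study.

Runs the full simulation harness (genotypes -> weights -> signature -> GRPs
-> phenotype -> GWAS -> cWAS test) over a small heritability grid with the
signature either fully or half known, then a cross-tissue null where the
phenotype is driven by an independent second tissue.
"""

from cwas.simulator import (SimulationSpec, run_cross_tissue_null,
                            run_replicates)

spec = SimulationSpec(n_individuals=1500, n_snps=500, n_genes=50,
                      n_celltypes=5, h2_grid=(0.0, 0.02, 0.05),
                      signature_fractions=(0.5, 1.0), n_replicates=50,
                      min_signature_genes=20, seed=4)
report = run_replicates(spec)
print(report.table.round(3).to_string(index=False))
print("\npower: fraction of replicates where the causal cell type is "
      "Bonferroni-significant (at h2=0 this is the null rejection rate); "
      "top_rate: how often it ranks most significant; fir: rejections among "
      "non-causal cell types. Halving the known signature should cost power "
      "at low h2, never gain it.\n")

null_spec = SimulationSpec(n_individuals=1000, n_snps=500, n_genes=24,
                           n_celltypes=5, min_signature_genes=10, seed=5)
rates = run_cross_tissue_null(null_spec, h2_grid=(0.1,), n_replicates=100,
                              fresh_genotypes=True)
print(rates.to_string(index=False))
print("\nCross-tissue null: tissue-A cell types carry no signal, so each "
      "rate should sit near the nominal 5% level.")
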