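"""Cis-eQTL scan with per-cohort models and fixed-effect meta-analysis.

Maps SNPs within 1 Mb of the probe anchor against probe-level expression in
three cohorts separately, combines them by inverse-variance weighting, and
applies Bonferroni / Benjamini-Hochberg multiplicity control.
"""
import pandas as pd

import spliceqtl as sq

gene = sq.default_gene_model()
genotypes = sq.simulate_genotypes(600, [(3, 0.3, 0.95)], 3, seed=31)
covariates = sq.simulate_cohort(600, 250, seed=32)
spec = sq.flip_effect_spec("snp0001", gene)  # snp0001 and its LD block are causal
abundances = sq.simulate_variant_abundances(genotypes, covariates, gene, spec, seed=33)
ms = sq.render_measurements(abundances, gene, sq.probe_junction_of(gene), 0.1, seed=34)

expr = pd.DataFrame({"probe_log2": ms.probe_log2})
anchors = pd.DataFrame(
    {"feature_id": ["probe_log2"], "chrom": gene.chrom,
     "position": [gene.introns[-1][0]]}  # the probe's junction position
)
results, table = sq.map_cis_qtl(expr, anchors, genotypes, covariates)

cols = ["snp_id", "meta_beta", "meta_se", "meta_p", "bonferroni_p", "fdr",
        "genotype_high_expression", "significant"]
print(table[cols].round(4).to_string(index=False))
print("\nsnp0001 and its LD-block partners carry the planted effect: positive")
print("meta_beta, Bonferroni-significant, with the alt homozygote as the")
print("genotype of high expression. Independent SNPs stay null.")
print(f"\nper-cohort betas for snp0001: "
      f"{table.loc[table.snp_id == 'snp0001', ['beta_cohort1', 'beta_cohort2', 'beta_cohort3']].round(3).to_dict('records')[0]}")
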