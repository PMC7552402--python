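"""Simulate a multi-cohort genotype + clinical dataset with planted LD blocks.

Builds Hardy-Weinberg genotypes (two LD blocks plus independent SNPs), a
COPD case/control covariate table, and splice-variant abundances under the
default direction-flip effects, then prints what was planted.
"""
import numpy as np

import spliceqtl as sq

genotypes = sq.simulate_genotypes(
    n_samples=300,
    block_spec=[(4, 0.3, 0.95), (3, 0.2, 0.9)],  # (n_snps, MAF, within-block r2)
    n_independent=3,
    seed=11,
)
print(f"{len(genotypes.snp_ids)} SNPs x {len(genotypes.samples)} samples")
print("empirical MAF:", genotypes.empirical_maf().round(3))
r2 = sq.ld_r2(genotypes.dosage_of("snp0001"), genotypes.dosage_of("snp0002"))
print(f"r2 within block 1: {r2:.3f} (target 0.95)")

covariates = sq.simulate_cohort(300, n_copd=120, seed=12)
copd = covariates["fev1_fvc_ratio"] < 70
print(f"\n{copd.sum()} COPD (FEV1/FVC < 70) vs {(~copd).sum()} non-COPD")
print(covariates.groupby(copd.map({True: "COPD", False: "non-COPD"}))[
    ["age", "pack_years", "fev1_pct_pred", "fev1_fvc_ratio"]].median().round(2))

gene = sq.default_gene_model()
spec = sq.flip_effect_spec("snp0001", gene)
abundances = sq.simulate_variant_abundances(genotypes, covariates, gene, spec, seed=13)
print("\nmean splice-variant abundance by snp0001 dosage")
print("(coding V1 rises with alt dosage; intron-retaining V2/V3 fall):")
for d in (0, 1, 2):
    mask = np.round(genotypes.dosage_of("snp0001")) == d
    print(f"  dosage {d}: {abundances[mask].mean().round(2).to_dict()}")
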