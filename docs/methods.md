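# Methods

This note documents the models implemented in `spliceqtl`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All genomic coordinates are 1-based inclusive (SAM POS / GFF3 convention);
no half-open conversion occurs anywhere. An intron is stored as the first
through last intronic base. SAM reading/writing goes through pysam, GFF3
parsing through gffutils, and every delimited output is a single-header TSV
written with a fixed float format so seeded runs are byte-reproducible.

## Gene model

The default gene mirrors a small three-exon cytokine gene: exons of
200/180/420 bp separated by short introns (40 and 30 bp), on the + strand of
chr22. Three transcript variants: V1 (coding) splices both introns; V2
retains the second intron; V3 retains the first. A junction-targeted probe
reads out the last (exon2–exon3) junction and therefore detects only V1 and
V3. Intron retention is represented structurally: a retained intron merges
its flanking exons into one alignment block of that variant's transcript,
which is exactly what makes the variant invisible to reads spanning that
junction.

## Synthetic cohort

### Genotypes

Dosages are sums of two independent haplotypes, each drawn under
Hardy–Weinberg proportions. LD within a declared block is induced by a
copula: every haplotype draws one shared uniform per block and each SNP
keeps it with probability `s`, resampling a fresh uniform otherwise. Two
SNPs then share the latent uniform with probability `s²`, which equals the
Pearson correlation of their allele indicators and of their dosages; the LD
`r²` (squared dosage correlation) is therefore `s⁴`, so the generator sets
`s = r²_target^(1/4)`. `r² = 1` degenerates to duplicated haplotypes. The
calibration is verified empirically in the test suite at n = 4000.

### Covariates

Marginals approximate a lung-resection cohort: age ~ N(63, 8) truncated to
41–88 years, pack-years log-normal around 38, 57% male, 30% current
smokers, FEV1/FVC ~ N(58, 9) truncated below 70 for cases and N(75.5, 4)
truncated to [70, 95] for controls, GOLD stage graded from FEV1 %predicted
(≥80 / 50–80 / 30–50 / <30). These are configuration, not claims about any
real cohort; every generated subject passes the downstream inclusion
filters by construction so that sample sizes are what the caller asked for.

### Expression model

Log abundance of variant v in sample i:

    log μ_iv = log(baseline_v) + Σ_snp β_{snp,v}·dosage_i
             + shift_v·1[COPD_i] + γ_age·(age_i − 60) + γ_sex·male_i
             + γ_smk·current_i + ε,   ε ~ N(0, noise_sd)

Age is centred at 60 so baselines stay interpretable. Defaults:
noise_sd = 0.2, γ = (0.003, 0.05, 0.08).

**The default flip scenario.** The alt allele of the causal SNP carries
β = +0.30 on the coding variant and −0.25 on each intron-retaining variant,
with baselines 10 (V1), 32 (V2) and 8 (V3). The asymmetry is deliberate:
with a log-linear model, a probe-detected sum (V1+V3) that rises over the
whole dosage range 0–2 *and* a total (V1+V2+V3) that falls requires the
probe-invisible variant (V2, which retains the probe's target intron) to
carry most of the non-coding mass. Making the two non-coding baselines equal
at any magnitude makes the probe signal non-monotone in dosage (the coding
exponential overtakes the non-coding decay inside the dosage range), so no
symmetric choice can produce the sign pattern the flip scenario exists to
test. With the chosen defaults the sign conditions hold analytically at
every dosage step, which the test suite checks in closed form before any
simulation.

### Reads and measurements

Reads are single-end, error-free, uniformly placed along each variant's
transcript, with per-variant counts Poisson(abundance × depth_factor). A
read overlapping a spliced junction gets an N operation whose reference span
equals the intron; reads within retained introns are contiguous M. The
closed-form split-read expectation per junction is
Σ_v abundance_v × depth × (R−1)/(L_v−R+1) (R−1 bridging start positions out
of L_v−R+1), and the renderer is held to it within Poisson error in the
tests. A count-level sampler (`sample_junction_counts`) draws Poisson counts
directly around the same expectation — distributionally identical to
rendering plus counting and used where many simulated cohorts are needed;
the read-level path is exercised separately and in the SAM round-trip tests.

Probe intensity is log2 of the summed abundances of the variants splicing
the probe junction plus Gaussian noise (default sd 0.1 log2 units). Total
FPKM sums per-variant FPKM with each variant's own exon-model length
(fragments × 10⁹ / (length × library size)), which preserves the FPKM
scale-invariance property exactly.

The generator does **not** emulate: paired ends, sequencing errors, mapping
ambiguity, positional bias, overdispersion beyond Poisson, population
stratification, or realistic allele-frequency spectra. Passing tests
demonstrate the statistical machinery is correct under its stated model, not
that real data meet that model.

## Junction quantification

One junction per CIGAR N operation; M/D/N/=/X consume reference, I/S/H do
not; `=`/`X` are treated as M; P (padding) is rejected as unsupported.
Junctions are grouped by (chrom, strand, intron start, intron end), with
strand taken from the annotated host gene (reads are unstranded); a junction
is assigned to the gene whose span contains the whole intron, the smallest
span winning ties (logged). Unassigned junctions keep strand `.` and are
dropped from normalization. Duplicate reads are not collapsed. A minimum
mapping quality is configurable; there is no overhang filter by default
(configurable upstream by the caller filtering reads).

### Normalization

The two corrections — library size and gene-wise transcript abundance — are
implemented as:

    scaled(i,j) = raw(i,j) / (L_i / median_k L_k)
    g_i(gene)   = A_i / median_k A_k,   A_i = library-scaled reads on the gene
    norm(i,j)   = scaled(i,j) / max(g_i, ε),   ε = 1e-8

with L_i the per-sample mapped-read total and A_i the per-sample
library-scaled count of reads overlapping the host gene (a transcript-
abundance proxy). When per-gene read totals are unavailable the gene's own
split-read total substitutes for A_i. The gene factor is deliberately based
on *all* reads on the gene, not on its split-read total: for a two-junction
gene a split-read-total denominator turns the two normalized junction values
into within-sample shares that sum to a constant, which would make it
structurally impossible for both junctions to move in the same direction —
yet that is precisely the observable pattern when a coding variant rises
while the gene total falls. Both invariances (pure library-size scaling and
pure gene-abundance scaling leave normalized values exactly unchanged) are
asserted bit-exactly in the tests.

## Cohort definition, adjustment, group tests

COPD is FEV1/FVC < 70%, non-COPD ≥ 70% (boundary inclusive); excluded:
age ≤ 40 (the inclusion criterion "> 40" read strictly), pack-years < 5,
never smokers, other lung disease, or missing classification fields (each
exclusion carries a reason). Adjustment is a per-feature Huber M-estimator
(tuning constant 1.345, MAD scale, iterated to coefficient tolerance 1e-10
via statsmodels RLM) on intercept + age + sex + smoking indicator; the
adjusted value is residual + fitted intercept so units and location are
preserved, and the operation is idempotent to solver tolerance. Collinear
terms (e.g. a single-sex cohort) are dropped with a warning. Group
differences use the two-sided Mann–Whitney U — exact null distribution when
both groups are ≤ 8 and tie-free, normal approximation with tie and
continuity correction otherwise — with per-GOLD-stage vs non-COPD
comparisons implemented the same way (the severity breakdown's test is an
assumption; nothing stronger is claimed for it). Lung-function correlations
are Spearman with average-rank ties; constant inputs report a missing rho.

## QTL engine

Per cohort: OLS of the feature on dosage plus age, sex and a smoking
indicator; two-sided t test on the dosage coefficient; pairwise deletion of
missing values; untestable when fewer than covariates + 3 complete samples
remain or dosage does not vary. The expression matrix is taken as-is — the
caller chooses the transform (the pipeline feeds log2 probe intensity and
log2 FPKM; normalized junction counts enter linearly). The eQTL path encodes
smoking as current-vs-ex within the included cohort; the spliceQTL path
reads the same indicator as current-smoking status. The cis window is
±1 Mb around the feature anchor, boundary inclusive; MAF < 0.05 SNPs are
removed (strict inequality, folded at 0.5). Cohorts are combined by
inverse-variance-weighted fixed effects — the minimal-assumption choice for
a three-cohort design where no heterogeneity model is specified — with a
Wald p. Multiplicity control: Bonferroni over all tested SNP–feature pairs
(per-feature families available), with BH FDR emitted alongside so both
thresholds are inspectable; the significance flag uses Bonferroni < 0.05.
The implementation is held to a statsmodels OLS oracle at 1e-8 on random
designs, to a simulated type-I error band at n = 300, and to unbiased
recovery of a planted β = 0.3.

## LD and GWAS cross-reference

r² is the squared Pearson correlation of dosages over pairwise-complete
samples (composite LD; no phasing — a deliberate divergence from
haplotype-based panel estimators, since only dosages exist in this data
model; panel-derived block assignments are therefore not expected to match
numerically). Blocks are built greedily: the most significant unassigned SNP
(ascending meta p, genomic position breaking ties) seeds a block and
captures every unassigned SNP with r² strictly > 0.8; seeds that capture
nobody are independent signals, so blocks and independents always partition
the input. Proxy lookup uses r² ≥ threshold (LDproxy convention) within a
500 kb window. GWAS cross-referencing reports direct catalog hits and
proxy hits per eSNP with trait, study and r².

## Direction reconciliation

`direction_profile` fits the identical dosage model per measurement mode
(probe log2, log2 total FPKM, each normalized junction) and derives the
genotype of high expression from the effect sign (alt homozygote for β > 0).
The flip flag requires *both* probe and total effects significant at a
configurable gate (default p < 0.05) with opposite signs — the gate keeps
sign-flipping noise on null effects from being reported as a flip. Junction
directions are reported separately per junction. Recoding ref/alt flips
every beta and genotype string but never the flip flag.

## Pipeline and determinism

The orchestrator validates its config (pydantic schema) before any stage
runs, derives per-stage child seeds from one master seed, executes
simulate → quantify → prep → diffexp → eQTL → spliceQTL → LD blocks →
GWAS cross-reference → reconcile, and writes a manifest (config, seeds,
version, artifact list) with no timestamps. Identical configs produce
byte-identical TSVs. Default problem sizes (150 samples, 12 SNPs, read
depth factor 8 when rendering) keep a full run under a second while leaving
the planted effects comfortably detectable; the reconciliation checks run at
n = 500 with the count-level sampler, matching the scale at which the flip
pattern is near-deterministic under the default effects.

## Known limitations

- The r² estimator and the greedy block construction are not those of
  haplotype-panel tools; block counts on real data will differ from
  panel-based assignments.
- The Bonferroni family is the run's own test count; genome-wide scans
  would need a different family definition.
- No trans-QTL, permutation p-values, interaction terms, genotype
  imputation, or BAM/CRAM binary input (SAM text only).
- The junction normalization formula is one defensible reading of
  "library size and gene-wise transcript abundance" correction; its
  gene-abundance denominator is chosen for interpretability as relative
  splice usage and for the structural reason given above.
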