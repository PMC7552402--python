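"""Synthetic multi-cohort data generator.

Emulates the statistical structure a splice-aware cis-eQTL analysis assumes:
genotypes in LD blocks under Hardy-Weinberg equilibrium, clinical covariates
of a COPD case/control cohort, splice-variant abundances of a small
three-exon gene with planted genotype and disease effects, aligned split
reads, and probe-style / total (FPKM) expression measurements.

LD within a block is induced by a haplotype-level copula: each haplotype
draws one shared uniform per block, and each SNP keeps that shared uniform
with probability ``s`` (resampling a fresh one otherwise). Two SNPs then
share the latent uniform with probability ``s**2``, which equals the Pearson
correlation of their allele indicators (and of their dosages); the LD
``r**2`` is its square, so ``s = r2_target ** 0.25``.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    EffectSpec,
    GeneModel,
    GenotypeMatrix,
    InvalidParameterError,
    Junction,
    JunctionKey,
    MeasurementSet,
    SpliceVariant,
)

_ALLELE_PAIRS = [("T", "C"), ("A", "G"), ("C", "A"), ("G", "T"), ("A", "C"), ("T", "G")]


def default_gene_model() -> GeneModel:
    """Three-exon gene with one coding and two intron-retention variants.

    V1 (coding) splices both introns; V2 retains the second intron (and is
    therefore invisible to a probe targeting the exon2-exon3 junction);
    V3 retains the first intron. Introns are short, as is typical for the
    small cytokine genes this emulates.
    """
    exons = [
        (24_000_001, 24_000_200),  # exon 1, 200 bp
        (24_000_241, 24_000_420),  # exon 2, 180 bp (intron 1: 40 bp)
        (24_000_451, 24_000_870),  # exon 3, 420 bp (intron 2: 30 bp)
    ]
    strand = "+"
    intron1 = (strand, 24_000_201, 24_000_240)
    intron2 = (strand, 24_000_421, 24_000_450)
    variants = [
        SpliceVariant("V1", True, frozenset({intron1, intron2})),
        SpliceVariant("V2", False, frozenset({intron1}), frozenset({1})),
        SpliceVariant("V3", False, frozenset({intron2}), frozenset({0})),
    ]
    return GeneModel("GENE1", "chr22", strand, exons, variants)


def probe_junction_of(gene: GeneModel) -> JunctionKey:
    """The junction a junction-targeted probe reads out: the last one
    (exon2-exon3 in the default three-exon model)."""
    return gene.junction_keys[-1]


def simulate_genotypes(
    n_samples: int,
    block_spec: Sequence[tuple[int, float, float]],
    n_independent: int = 0,
    seed: int = 0,
    *,
    chrom: str = "chr22",
    start_pos: int = 23_600_000,
    spacing_bp: int = 2_000,
    independent_maf_range: tuple[float, float] = (0.1, 0.5),
) -> GenotypeMatrix:
    """Simulate Hardy-Weinberg dosages with block LD structure.

    Parameters
    ----------
    block_spec
        One ``(n_snps, maf, within_block_r2)`` tuple per LD block.
    n_independent
        Number of mutually uncorrelated SNPs appended after the blocks.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    if n_independent < 0:
        raise InvalidParameterError("n_independent must be >= 0")
    for n_snps, maf, r2 in block_spec:
        if n_snps <= 0:
            raise InvalidParameterError("block n_snps must be positive")
        if not (0 < maf <= 0.5):
            raise InvalidParameterError(f"maf must lie in (0, 0.5], got {maf}")
        if not (0 <= r2 <= 1):
            raise InvalidParameterError(f"within_block_r2 must lie in [0, 1], got {r2}")

    rng = np.random.default_rng(seed)
    columns: list[np.ndarray] = []
    mafs: list[float] = []
    for n_snps, maf, r2 in block_spec:
        s = float(r2) ** 0.25
        shared = rng.uniform(size=(n_samples, 2))
        dos = np.empty((n_samples, n_snps))
        for j in range(n_snps):
            keep = rng.uniform(size=(n_samples, 2)) < s
            u = np.where(keep, shared, rng.uniform(size=(n_samples, 2)))
            dos[:, j] = (u < maf).sum(axis=1)
        columns.append(dos)
        mafs.extend([maf] * n_snps)
    if n_independent:
        ind_maf = rng.uniform(*independent_maf_range, size=n_independent)
        alleles = rng.uniform(size=(n_samples, 2, n_independent)) < ind_maf
        columns.append(alleles.sum(axis=1).astype(float))
        mafs.extend(ind_maf.tolist())

    dosages = np.hstack(columns) if columns else np.empty((n_samples, 0))
    n_total = dosages.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:04d}" for i in range(n_total)],
            "chrom": chrom,
            "position": [start_pos + i * spacing_bp for i in range(n_total)],
            "ref": [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(n_total)],
            "alt": [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(n_total)],
            "maf": mafs,
        }
    )
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def simulate_cohort(
    n_samples: int,
    n_copd: int,
    seed: int = 0,
    *,
    cohorts: Sequence[str] = ("cohort1", "cohort2", "cohort3"),
) -> pd.DataFrame:
    """Simulate a clinical covariate table for a COPD case/control cohort.

    Marginal distributions approximate a resection-surgery cohort: ages
    centred in the mid-sixties, heavy smoking histories, FEV1/FVC below 70%
    for cases (GOLD stage graded from FEV1 %predicted) and >= 70% for
    controls. Every generated subject satisfies the downstream inclusion
    filters (age > 40, >= 5 pack-years, current or ex-smoker).
    """
    if n_copd > n_samples:
        raise InvalidParameterError("n_copd cannot exceed n_samples")
    rng = np.random.default_rng(seed)
    copd = np.zeros(n_samples, dtype=bool)
    copd[rng.permutation(n_samples)[:n_copd]] = True

    age = np.clip(rng.normal(63, 8, n_samples), 41, 88).round(1)
    pack_years = np.clip(rng.lognormal(np.log(38), 0.45, n_samples), 5, 150).round(1)
    sex = np.where(rng.uniform(size=n_samples) < 0.57, "male", "female")
    smoking = np.where(rng.uniform(size=n_samples) < 0.3, "current", "ex")

    ratio = np.where(
        copd,
        np.clip(rng.normal(58, 9, n_samples), 30, 69.9),
        np.clip(rng.normal(75.5, 4, n_samples), 70, 95),
    ).round(2)
    fev1 = np.where(
        copd,
        np.clip(rng.normal(62, 13, n_samples), 15, 90),
        np.clip(rng.normal(94, 12, n_samples), 60, 130),
    ).round(2)

    gold = np.full(n_samples, "none", dtype=object)
    stage = np.select(
        [fev1 >= 80, fev1 >= 50, fev1 >= 30], ["1", "2", "3"], default="4"
    )
    gold[copd] = stage[copd]

    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n_samples)],
            "cohort": rng.choice(list(cohorts), size=n_samples),
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "pack_years": pack_years,
            "fev1_pct_pred": fev1,
            "fev1_fvc_ratio": ratio,
            "gold_stage": gold,
            "other_lung_disease": False,
        }
    )


def flip_effect_spec(
    causal_snp: str,
    gene: Optional[GeneModel] = None,
    *,
    noise_sd: float = 0.2,
) -> EffectSpec:
    """Default direction-flip scenario.

    The alt allele raises the coding variant (+0.30 per dosage unit on the
    log scale) and lowers each intron-retention variant (-0.25). The
    probe-invisible variant (V2, which retains the probe's target intron)
    carries most of the non-coding mass (baseline 32 vs 8), so that over the
    whole dosage range 0-2 the probe-detected sum (V1+V3) rises while the
    all-variant total falls -- the signature that makes junction-restricted
    and total expression disagree in sign.
    """
    gene = gene or default_gene_model()
    coding = [v.variant_id for v in gene.variants if v.coding]
    probe = probe_junction_of(gene)
    noncoding = [v.variant_id for v in gene.variants if not v.coding]
    invisible = [
        v.variant_id
        for v in gene.variants
        if not v.coding and probe not in v.spliced_junctions
    ]
    baseline = {}
    beta = {}
    for v in gene.variants:
        if v.coding:
            baseline[v.variant_id] = 10.0
            beta[(causal_snp, v.variant_id)] = 0.30
        else:
            baseline[v.variant_id] = 32.0 if v.variant_id in invisible else 8.0
            beta[(causal_snp, v.variant_id)] = -0.25
    return EffectSpec(
        baseline=baseline,
        beta=beta,
        disease_shift={coding[0]: 0.3},
        covariate_coefs={
            v: {"age": 0.003, "sex_male": 0.05, "smoking_current": 0.08}
            for v in baseline
        },
        noise_sd=noise_sd,
    )


def concordant_effect_spec(
    causal_snp: str,
    gene: Optional[GeneModel] = None,
    *,
    beta: float = 0.2,
    noise_sd: float = 0.2,
) -> EffectSpec:
    """All variants respond to the alt allele with the same positive beta."""
    gene = gene or default_gene_model()
    return EffectSpec(
        baseline={v.variant_id: 15.0 for v in gene.variants},
        beta={(causal_snp, v.variant_id): beta for v in gene.variants},
        noise_sd=noise_sd,
    )


def null_effect_spec(gene: Optional[GeneModel] = None, *, noise_sd: float = 0.2) -> EffectSpec:
    """No genotype, disease or covariate effects at all."""
    gene = gene or default_gene_model()
    return EffectSpec(
        baseline={v.variant_id: 15.0 for v in gene.variants}, noise_sd=noise_sd
    )


def simulate_variant_abundances(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    gene: GeneModel,
    spec: EffectSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Samples x variants abundance table under the log-linear model."""
    spec.validate_for(gene)
    for snp_id, variant_id in spec.beta:
        if snp_id not in genotypes.snp_ids:
            raise KeyError(f"EffectSpec references unknown SNP {snp_id!r}")
        gene.variant(variant_id)  # raises KeyError on unknown variant

    cov = covariates.set_index("sample_id").loc[genotypes.samples]
    is_copd = (cov["fev1_fvc_ratio"] < 70).to_numpy(dtype=float)
    age_c = cov["age"].to_numpy(dtype=float) - 60.0
    male = (cov["sex"] == "male").to_numpy(dtype=float)
    current = (cov["smoking"] == "current").to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    n = len(genotypes.samples)
    out = {}
    for v in gene.variants:
        log_mu = np.full(n, np.log(spec.baseline[v.variant_id]))
        for (snp_id, variant_id), b in spec.beta.items():
            if variant_id == v.variant_id and b != 0.0:
                log_mu += b * np.nan_to_num(genotypes.dosage_of(snp_id))
        log_mu += spec.disease_shift.get(v.variant_id, 0.0) * is_copd
        coefs = spec.covariate_coefs.get(v.variant_id, {})
        log_mu += (
            coefs.get("age", 0.0) * age_c
            + coefs.get("sex_male", 0.0) * male
            + coefs.get("smoking_current", 0.0) * current
        )
        if spec.noise_sd > 0:
            log_mu = log_mu + rng.normal(0.0, spec.noise_sd, n)
        out[v.variant_id] = np.exp(log_mu)
    return pd.DataFrame(out, index=list(genotypes.samples))


@dataclass
class AlignedRead:
    """Minimal single-end alignment record (always mapped, forward)."""

    qname: str
    chrom: str
    pos: int          # 1-based leftmost reference position
    cigar: str
    flag: int = 0
    mapq: int = 255

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4)


def _transcript_layout(gene: GeneModel, variant: SpliceVariant):
    """Per-variant genomic blocks and cumulative transcript offsets."""
    blocks = gene.variant_blocks(variant)
    lengths = [e - s + 1 for s, e in blocks]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return blocks, lengths, offsets


def _cigar_for(gene, variant, blocks, lengths, offsets, t_start: int, read_len: int) -> tuple[int, str]:
    """Map a transcript interval [t_start, t_start+read_len) to (POS, CIGAR)."""
    remaining = read_len
    ops: list[str] = []
    pos = None
    b = int(np.searchsorted(offsets, t_start, side="right")) - 1
    within = t_start - offsets[b]
    while remaining > 0:
        block_start, block_end = blocks[b]
        if pos is None:
            pos = block_start + within
        take = min(remaining, lengths[b] - within)
        ops.append(f"{take}M")
        remaining -= take
        if remaining > 0:
            gap = blocks[b + 1][0] - blocks[b][1] - 1
            ops.append(f"{gap}N")
            b += 1
            within = 0
    return pos, "".join(ops)


def render_reads(
    abundances: pd.DataFrame,
    gene: GeneModel,
    read_length: int = 75,
    depth_factor: float = 100.0,
    seed: int = 0,
) -> Iterator[tuple[str, list[AlignedRead]]]:
    """Yield (sample_id, reads) with split reads across spliced junctions.

    Per sample and variant the read count is Poisson(abundance *
    depth_factor); reads are single-end, error-free and placed uniformly
    along the variant's transcript. A read overlapping a spliced junction
    carries an N operation whose reference span equals the intron.
    """
    if read_length <= 0:
        raise InvalidParameterError("read_length must be positive")
    rng = np.random.default_rng(seed)
    layouts = {v.variant_id: _transcript_layout(gene, v) for v in gene.variants}
    cigar_cache: dict[tuple[str, int], tuple[int, str]] = {}
    for sample in abundances.index:
        reads: list[AlignedRead] = []
        serial = itertools.count()
        for v in gene.variants:
            blocks, lengths, offsets = layouts[v.variant_id]
            tlen = int(offsets[-1])
            rlen = min(read_length, tlen)
            n_reads = rng.poisson(abundances.at[sample, v.variant_id] * depth_factor)
            if n_reads == 0:
                continue
            starts = rng.integers(0, tlen - rlen + 1, size=n_reads)
            for t in starts:
                key = (v.variant_id, int(t))
                hit = cigar_cache.get(key)
                if hit is None:
                    hit = _cigar_for(gene, v, blocks, lengths, offsets, int(t), rlen)
                    cigar_cache[key] = hit
                pos, cigar = hit
                reads.append(
                    AlignedRead(
                        qname=f"{sample}.{v.variant_id}.{next(serial)}",
                        chrom=gene.chrom,
                        pos=pos,
                        cigar=cigar,
                    )
                )
        yield sample, reads


def junction_overlap_probability(
    gene: GeneModel, variant: SpliceVariant, key: JunctionKey, read_length: int
) -> float:
    """P(a uniformly placed read from `variant` spans junction `key`).

    With transcript length L and read length R there are R-1 start positions
    bridging the splice point out of L-R+1, requiring >= 1 aligned base on
    each side.
    """
    if key not in variant.spliced_junctions:
        return 0.0
    L = gene.variant_length(variant)
    R = min(read_length, L)
    if R < 2:
        return 0.0
    return (R - 1) / (L - R + 1)


def expected_junction_counts(
    abundances: pd.DataFrame,
    gene: GeneModel,
    read_length: int = 75,
    depth_factor: float = 100.0,
) -> pd.DataFrame:
    """Closed-form expected split-read counts (samples x junction labels)."""
    cols = {}
    for i, key in enumerate(gene.junction_keys):
        jl = gene.junction(i).label
        total = np.zeros(len(abundances))
        for v in gene.variants:
            p = junction_overlap_probability(gene, v, key, read_length)
            if p:
                total += abundances[v.variant_id].to_numpy() * depth_factor * p
        cols[jl] = total
    return pd.DataFrame(cols, index=abundances.index)


def sample_junction_counts(
    abundances: pd.DataFrame,
    gene: GeneModel,
    read_length: int = 75,
    depth_factor: float = 100.0,
    seed: int = 0,
    *,
    background_reads: float = 50_000.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Count-level emulation of render_reads + junction counting.

    Draws Poisson split-read counts around their closed-form expectation,
    plus per-sample gene read totals and library sizes (gene reads plus a
    Poisson background of off-gene reads). Distributionally identical to
    rendering reads and counting CIGAR N operations, at a fraction of the
    cost; use the read-level path when actual SAM output is needed.
    """
    rng = np.random.default_rng(seed)
    expect = expected_junction_counts(abundances, gene, read_length, depth_factor)
    counts = pd.DataFrame(
        rng.poisson(expect.to_numpy()),
        index=expect.index,
        columns=expect.columns,
    )
    gene_mu = abundances.sum(axis=1).to_numpy() * depth_factor
    gene_reads = pd.Series(rng.poisson(gene_mu), index=abundances.index, name=gene.gene_id)
    library = pd.Series(
        gene_reads.to_numpy() + rng.poisson(background_reads, len(abundances)),
        index=abundances.index,
        name="library_size",
    )
    return counts, gene_reads, library


def render_measurements(
    abundances: pd.DataFrame,
    gene: GeneModel,
    probe_junction: JunctionKey,
    noise_sd_probe: float = 0.1,
    seed: int = 0,
    *,
    library_sizes: Optional[pd.Series] = None,
    depth_factor: float = 100.0,
    mean_library_size: float = 2e7,
) -> MeasurementSet:
    """Probe-style log2 intensity and total FPKM for one gene.

    probe_log2 = log2(sum of abundances of variants splicing the probe's
    junction) + Normal(0, noise_sd_probe). total_fpkm sums per-variant FPKM
    (expected fragments = abundance * depth_factor, each variant normalized
    by its own exon-model length in kb and the library size in millions).
    """
    if probe_junction not in set(gene.junction_keys):
        raise InvalidParameterError(
            f"probe junction {probe_junction} is not a junction of {gene.gene_id}"
        )
    rng = np.random.default_rng(seed)
    detected = [v.variant_id for v in gene.variants_splicing(probe_junction)]
    probe_sum = abundances[detected].sum(axis=1)
    probe = np.log2(probe_sum)
    if noise_sd_probe > 0:
        probe = probe + rng.normal(0.0, noise_sd_probe, len(probe))

    if library_sizes is None:
        library_sizes = pd.Series(
            np.maximum(
                rng.normal(mean_library_size, mean_library_size / 20, len(abundances)),
                1.0,
            ).round(),
            index=abundances.index,
            name="library_size",
        )
    fpkm = np.zeros(len(abundances))
    for v in gene.variants:
        frags = abundances[v.variant_id].to_numpy() * depth_factor
        fpkm += frags * 1e9 / (gene.variant_length(v) * library_sizes.to_numpy())
    return MeasurementSet(
        probe_log2=pd.Series(probe, index=abundances.index, name="probe_log2"),
        total_fpkm=pd.Series(fpkm, index=abundances.index, name="total_fpkm"),
        library_sizes=library_sizes,
        probe_junction=probe_junction,
    )
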