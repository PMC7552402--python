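"""Core data structures shared across the pipeline.

Coordinate convention used everywhere in this package: 1-based, inclusive
reference coordinates (SAM POS and GFF3 style). An intron spanning reference
bases 150..349 is stored as ``(intron_start=150, intron_end=349)`` and no
half-open conversion happens anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: (strand, intron_start, intron_end) -- the identity of a splice junction.
JunctionKey = tuple[str, int, int]


class InvalidParameterError(ValueError):
    """Raised when an operation receives out-of-domain parameters."""


class ConfigurationError(ValueError):
    """Raised when a specification (effects, pipeline config) is incomplete."""


@dataclass(frozen=True)
class Junction:
    """A splice junction, identified by the intron it spans.

    ``strand`` is ``'+'``/``'-'`` once annotated to a host gene, ``'.'``
    (unknown) before annotation.
    """

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise InvalidParameterError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )

    @property
    def key(self) -> JunctionKey:
        return (self.strand, self.intron_start, self.intron_end)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}:{self.strand}"


@dataclass(frozen=True)
class SpliceVariant:
    """One transcript variant of a gene.

    ``spliced_junctions`` holds the junction keys the variant produces;
    ``retained_introns`` holds 0-based indices of gene introns the variant
    keeps (intron retention). Together they partition the gene's introns.
    """

    variant_id: str
    coding: bool
    spliced_junctions: frozenset[JunctionKey]
    retained_introns: frozenset[int] = frozenset()


@dataclass
class GeneModel:
    """Exon structure of a gene plus its splice variants.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted and
    non-overlapping. The coding variant must splice every intron.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Sequence[tuple[int, int]]
    variants: Sequence[SpliceVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InvalidParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = [tuple(int(x) for x in e) for e in self.exons]
        for s, e in exons:
            if s > e:
                raise InvalidParameterError(f"exon {s}-{e} has start > end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise InvalidParameterError("exons must be sorted and non-overlapping")
        self.exons = tuple(exons)
        all_keys = set(self.junction_keys)
        n_introns = len(self.introns)
        if self.variants and not any(v.coding for v in self.variants):
            raise InvalidParameterError("at least one variant must be coding")
        for v in self.variants:
            retained_keys = {self.junction_key(i) for i in v.retained_introns}
            if v.spliced_junctions & retained_keys:
                raise InvalidParameterError(
                    f"variant {v.variant_id}: spliced and retained introns overlap"
                )
            if v.spliced_junctions | retained_keys != all_keys:
                raise InvalidParameterError(
                    f"variant {v.variant_id}: spliced+retained do not partition introns"
                )
            if v.coding and len(v.spliced_junctions) != n_introns:
                raise InvalidParameterError(
                    f"coding variant {v.variant_id} must splice all introns"
                )

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def junction_key(self, intron_index: int) -> JunctionKey:
        s, e = self.introns[intron_index]
        return (self.strand, s, e)

    @property
    def junction_keys(self) -> list[JunctionKey]:
        return [self.junction_key(i) for i in range(len(self.introns))]

    def junction(self, intron_index: int) -> Junction:
        s, e = self.introns[intron_index]
        return Junction(self.chrom, self.strand, s, e, gene_id=self.gene_id)

    @property
    def junctions(self) -> list[Junction]:
        return [self.junction(i) for i in range(len(self.introns))]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def variant(self, variant_id: str) -> SpliceVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def variant_blocks(self, variant: SpliceVariant) -> list[tuple[int, int]]:
        """Genomic alignment blocks of the variant's transcript.

        Retained introns merge the flanking exons into a single block.
        """
        blocks = [list(self.exons[0])]
        for i in range(len(self.introns)):
            nxt = self.exons[i + 1]
            if i in variant.retained_introns:
                blocks[-1][1] = nxt[1]
            else:
                blocks.append(list(nxt))
        return [(s, e) for s, e in blocks]

    def variant_length(self, variant: SpliceVariant) -> int:
        return sum(e - s + 1 for s, e in self.variant_blocks(variant))

    def variants_splicing(self, key: JunctionKey) -> list[SpliceVariant]:
        return [v for v in self.variants if key in v.spliced_junctions]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele dosages with SNP metadata.

    ``snps`` is a DataFrame with columns ``snp_id, chrom, position, ref, alt,
    maf``; ``dosages`` is a float array of shape (n_samples, n_snps) with
    values in [0, 2] (NaN = missing).
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise InvalidParameterError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise InvalidParameterError("dosages must lie in [0, 2]")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise InvalidParameterError(
                    f"SNP positions must be strictly increasing on {chrom}"
                )
        self._index = {s: i for i, s in enumerate(self.snps["snp_id"])}

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not present in genotype matrix") from None

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(snp_id)]

    def snp_info(self, snp_id: str) -> pd.Series:
        return self.snps.iloc[self.index_of(snp_id)]

    def subset(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.index_of(s) for s in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def empirical_maf(self) -> np.ndarray:
        """Sample MAF per SNP: mean dosage / 2, folded at 0.5."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def to_frame(self) -> pd.DataFrame:
        """SNPs as rows, metadata columns then one column per sample."""
        dosage_cols = pd.DataFrame(
            self.dosages.T, columns=list(self.samples), index=self.snps.index
        )
        return pd.concat([self.snps, dosage_cols], axis=1)


#: Covariate table columns required by cohort classification and adjustment.
COVARIATE_COLUMNS = [
    "sample_id",
    "cohort",
    "age",
    "sex",
    "smoking",
    "pack_years",
    "fev1_pct_pred",
    "fev1_fvc_ratio",
    "gold_stage",
    "other_lung_disease",
]


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise ConfigurationError(f"covariate table missing columns: {missing}")
    bad = cov[(cov["fev1_fvc_ratio"] <= 0) | (cov["fev1_fvc_ratio"] > 100)]
    if len(bad):
        raise ConfigurationError(
            f"fev1_fvc_ratio must lie in (0, 100]; offending samples: "
            f"{list(bad['sample_id'].head())}"
        )
    return cov


@dataclass
class EffectSpec:
    """Generative effects for the synthetic cohort.

    log-abundance of variant v in sample i =
        log(baseline_v) + sum_snp beta[(snp, v)] * dosage_i(snp)
        + disease_shift_v * 1[COPD_i] + covariate terms + Normal(0, noise_sd)

    Covariate coefficients are per-variant dicts over ``age`` (centred at 60
    years), ``sex_male`` and ``smoking_current`` indicators.
    """

    baseline: dict[str, float]
    beta: dict[tuple[str, str], float] = field(default_factory=dict)
    disease_shift: dict[str, float] = field(default_factory=dict)
    covariate_coefs: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for v, b in self.baseline.items():
            if b <= 0:
                raise InvalidParameterError(f"baseline of {v} must be > 0, got {b}")

    def validate_for(self, gene: GeneModel) -> None:
        missing = [v.variant_id for v in gene.variants if v.variant_id not in self.baseline]
        if missing:
            raise ConfigurationError(
                f"EffectSpec missing baseline for variants: {missing}"
            )


@dataclass
class MeasurementSet:
    """Per-sample expression of one gene under the three measurement modes."""

    probe_log2: pd.Series
    total_fpkm: pd.Series
    junction_counts: Optional[pd.DataFrame] = None  # samples x junction labels
    library_sizes: Optional[pd.Series] = None
    gene_read_counts: Optional[pd.Series] = None
    normalized_junctions: Optional[pd.DataFrame] = None
    probe_junction: Optional[JunctionKey] = None


@dataclass
class QtlResult:
    """Single-cohort association of one SNP with one feature."""

    snp_id: str
    feature_id: str
    beta: float
    se: float
    p_value: float
    n: int
    cohort: Optional[str] = None
    genotype_high_expression: Optional[str] = None
    testable: bool = True


@dataclass
class MetaQtlResult:
    """Fixed-effect combination of per-cohort QTL results."""

    snp_id: str
    feature_id: str
    meta_beta: float
    meta_se: float
    meta_p: float
    n_total: int
    per_cohort: list[QtlResult] = field(default_factory=list)
    genotype_high_expression: Optional[str] = None
    bonferroni_p: Optional[float] = None
    fdr: Optional[float] = None
    significant: Optional[bool] = None
    testable: bool = True


@dataclass
class LdBlock:
    representative: str
    members: list[str]          # excludes the representative
    member_r2: dict[str, float]


@dataclass
class LdBlockSet:
    """Partition of SNPs into multi-SNP LD blocks plus independent signals."""

    blocks: list[LdBlock]
    independent: list[str]

    @property
    def all_snps(self) -> set[str]:
        out = set(self.independent)
        for b in self.blocks:
            out.add(b.representative)
            out.update(b.members)
        return out
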