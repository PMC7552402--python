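"""End-to-end orchestrator: simulate -> quantify -> prep -> QTL -> LD -> reconcile.

A single validated YAML/dict config drives every stage; all randomness flows
from one master seed through per-stage child seeds, and every artifact is
written with a stable float format, so re-running a config reproduces
byte-identical TSV outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import cohort as syn
from . import io as sio
from .expression import adjust_expression, classify_cohort, compare_groups, correlate_lung_function
from .junctions import JunctionCountMatrix, count_junctions, normalize_junction_counts
from .ld import cluster_ld_blocks, gwas_crossref, read_gwas_catalog
from .models import ConfigurationError, Junction
from .qtl import map_cis_qtl
from .reconcile import direction_profile

logger = logging.getLogger(__name__)

CHROM_LENGTHS = {"chr22": 51_000_000}


class GenotypeConfig(BaseModel):
    blocks: list[tuple[int, float, float]] = [(4, 0.3, 0.95), (3, 0.2, 0.9)]
    n_independent: int = Field(3, ge=0)
    chrom: str = "chr22"
    start_pos: int = 23_990_000
    spacing_bp: int = Field(2_000, gt=0)


class EffectConfig(BaseModel):
    mode: Literal["flip", "concordant", "null"] = "flip"
    causal_snp: Optional[str] = None  # default: first simulated SNP
    noise_sd: float = Field(0.2, ge=0)


class ReadConfig(BaseModel):
    render: bool = False  # write and re-quantify SAM files (slower) instead
    #                       of the count-level junction sampler
    read_length: int = Field(75, gt=0)
    depth_factor: float = Field(8.0, gt=0)


class QtlConfig(BaseModel):
    window_bp: int = Field(1_000_000, gt=0)
    maf: float = Field(0.05, ge=0, le=0.5)
    alpha: float = Field(0.05, gt=0, lt=1)
    family: Literal["global", "per_feature"] = "global"


class LdConfig(BaseModel):
    threshold: float = Field(0.8, ge=0, le=1)
    proxy_window_bp: int = Field(500_000, gt=0)


class PipelineConfig(BaseModel):
    seed: int = 1
    n_samples: int = Field(150, ge=10)
    n_copd: int = Field(60, ge=0)
    probe_noise_sd: float = Field(0.1, ge=0)
    measurement_depth: float = Field(100.0, gt=0)
    genotypes: GenotypeConfig = GenotypeConfig()
    effects: EffectConfig = EffectConfig()
    reads: ReadConfig = ReadConfig()
    qtl: QtlConfig = QtlConfig()
    ld: LdConfig = LdConfig()
    gwas_catalog: Optional[str] = None  # TSV path; None -> small built-in list
    profile_snps: Optional[list[str]] = None  # default: the causal SNP


def load_config(source: Union[str, Path, dict, PipelineConfig]) -> PipelineConfig:
    """Validate a config mapping / YAML file before any stage runs."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(source)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid pipeline config:\n{exc}") from None


_BUILTIN_CATALOG = pd.DataFrame(
    {
        "snp_id": ["rs9000001", "rs9000002", "rs9000003", "rs9000004"],
        "trait": ["COPD", "COPD", "FEV1", "FEV1/FVC"],
        "study": [
            "synthetic_gwas_a", "synthetic_gwas_b",
            "synthetic_gwas_c", "synthetic_gwas_d",
        ],
    }
)


def run_pipeline(config, out_dir) -> dict:
    """Execute every stage in order, writing artifacts and a manifest.

    Returns a summary dict (significant eSNP counts, LD-block counts, flip
    flags, artifact paths). Re-running with the same config and out_dir
    produces byte-identical TSV outputs.
    """
    cfg = load_config(config)
    if cfg.n_copd > cfg.n_samples:
        raise ConfigurationError("n_copd cannot exceed n_samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(8)]
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        sio.write_tsv(df, out / name, **kw)
        artifacts[name] = str(out / name)

    # -- simulate ------------------------------------------------------------
    gene = syn.default_gene_model()
    genotypes = syn.simulate_genotypes(
        cfg.n_samples, cfg.genotypes.blocks, cfg.genotypes.n_independent,
        seed=seeds[0], chrom=cfg.genotypes.chrom,
        start_pos=cfg.genotypes.start_pos, spacing_bp=cfg.genotypes.spacing_bp,
    )
    covariates = syn.simulate_cohort(cfg.n_samples, cfg.n_copd, seed=seeds[1])
    causal = cfg.effects.causal_snp or genotypes.snp_ids[0]
    if cfg.effects.mode == "flip":
        spec = syn.flip_effect_spec(causal, gene, noise_sd=cfg.effects.noise_sd)
    elif cfg.effects.mode == "concordant":
        spec = syn.concordant_effect_spec(causal, gene, noise_sd=cfg.effects.noise_sd)
    else:
        spec = syn.null_effect_spec(gene, noise_sd=cfg.effects.noise_sd)
    abundances = syn.simulate_variant_abundances(genotypes, covariates, gene, spec, seed=seeds[2])

    sio.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
    artifacts["genotypes.tsv"] = str(out / "genotypes.tsv")
    sio.write_vcf(genotypes, out / "genotypes.vcf",
                  chrom_length=CHROM_LENGTHS.get(cfg.genotypes.chrom, 300_000_000))
    artifacts["genotypes.vcf"] = str(out / "genotypes.vcf")
    save(covariates, "covariates.tsv")
    sio.write_gff3([gene], out / "gene_model.gff3")
    artifacts["gene_model.gff3"] = str(out / "gene_model.gff3")

    # -- quantify ------------------------------------------------------------
    if cfg.reads.render:
        stream = syn.render_reads(
            abundances, gene, cfg.reads.read_length, cfg.reads.depth_factor, seed=seeds[3]
        )
        sam_paths = sio.write_sample_sams(
            stream, out / "reads",
            chroms={gene.chrom: CHROM_LENGTHS.get(gene.chrom, 300_000_000)},
        )
        jcm = count_junctions({s: str(p) for s, p in sam_paths.items()}, [gene])
    else:
        counts, gene_reads, library = syn.sample_junction_counts(
            abundances, gene, cfg.reads.read_length, cfg.reads.depth_factor, seed=seeds[3]
        )
        jcm = JunctionCountMatrix(
            junctions=gene.junctions,
            samples=list(counts.index),
            raw_counts=counts,
            library_sizes=library,
            gene_read_counts=gene_reads.to_frame(gene.gene_id),
        )
    norm = normalize_junction_counts(jcm)

    meta = pd.DataFrame(
        [
            {"chrom": j.chrom, "strand": j.strand, "intron_start": j.intron_start,
             "intron_end": j.intron_end, "gene_id": j.gene_id or "unassigned"}
            for j in jcm.junctions
        ]
    )
    save(pd.concat([meta, jcm.raw_counts.T.reset_index(drop=True)], axis=1), "junction_counts.tsv")
    meta_n = meta[meta["gene_id"] != "unassigned"].reset_index(drop=True)
    save(pd.concat([meta_n, norm.values.T.reset_index(drop=True)], axis=1), "junction_normalized.tsv")
    save(jcm.library_sizes.to_frame(), "library_sizes.tsv", index_label="sample_id")

    # -- measurements --------------------------------------------------------
    probe_key = syn.probe_junction_of(gene)
    measurements = syn.render_measurements(
        abundances, gene, probe_key, cfg.probe_noise_sd, seed=seeds[4],
        depth_factor=cfg.measurement_depth,
    )
    measurements.junction_counts = jcm.raw_counts
    measurements.normalized_junctions = norm.values
    expr = pd.DataFrame(
        {"probe_log2": measurements.probe_log2,
         "total_log2fpkm": np.log2(measurements.total_fpkm)}
    )
    save(expr.T, "expression.tsv", index_label="feature_id")

    # -- cohort prep and differential expression -----------------------------
    labels = classify_cohort(covariates)
    included = labels.index[labels["label"] != "excluded"]
    adjusted = adjust_expression(expr.loc[included], covariates)
    gold = covariates.set_index("sample_id")["gold_stage"]
    diffexp = compare_groups(adjusted, labels, gold_stage=gold)
    save(diffexp, "diffexp.tsv")
    save(correlate_lung_function(adjusted, covariates, labels), "lung_function_correlation.tsv")
    save(labels.reset_index(), "cohort_labels.tsv")

    # -- eQTL and spliceQTL --------------------------------------------------
    intron_mid = [(s + e) // 2 for s, e in gene.introns]
    anchors_e = pd.DataFrame(
        {
            "feature_id": ["probe_log2", "total_log2fpkm"],
            "chrom": gene.chrom,
            "position": [intron_mid[-1], sum(gene.span) // 2],
        }
    )
    eqtl_results, eqtl_table = map_cis_qtl(
        expr, anchors_e, genotypes, covariates,
        window_bp=cfg.qtl.window_bp, maf=cfg.qtl.maf, alpha=cfg.qtl.alpha,
        family=cfg.qtl.family, smoking_mode="current_vs_ex",
    )
    save(eqtl_table, "eqtl_results.tsv")

    anchors_s = pd.DataFrame(
        {
            "feature_id": list(norm.values.columns),
            "chrom": gene.chrom,
            "position": [j.intron_start for j in norm.junctions],
        }
    )
    splice_results, splice_table = map_cis_qtl(
        norm.values, anchors_s, genotypes, covariates,
        window_bp=cfg.qtl.window_bp, maf=cfg.qtl.maf, alpha=cfg.qtl.alpha,
        family=cfg.qtl.family, smoking_mode="current",
    )
    save(splice_table, "spliceqtl_results.tsv")

    # -- LD blocks and GWAS cross-reference ----------------------------------
    sig = [r for r in eqtl_results + splice_results if r.significant]
    best_p: dict[str, float] = {}
    for r in sig:
        best_p[r.snp_id] = min(best_p.get(r.snp_id, np.inf), r.meta_p)
    esnps = sorted(best_p, key=lambda s: (best_p[s], genotypes.snp_info(s)["position"]))
    block_set = cluster_ld_blocks(esnps, genotypes, cfg.ld.threshold, meta_p=best_p)
    rows = []
    for b_id, b in enumerate(block_set.blocks, 1):
        rows.append({"block_id": f"block{b_id}", "representative": b.representative,
                     "member": b.representative, "r2": 1.0})
        rows += [
            {"block_id": f"block{b_id}", "representative": b.representative,
             "member": m, "r2": b.member_r2[m]}
            for m in b.members
        ]
    for s in block_set.independent:
        rows.append({"block_id": "independent", "representative": s, "member": s, "r2": 1.0})
    save(pd.DataFrame(rows, columns=["block_id", "representative", "member", "r2"]), "ld_blocks.tsv")

    catalog = read_gwas_catalog(cfg.gwas_catalog) if cfg.gwas_catalog else _BUILTIN_CATALOG
    xref, xref_summary = gwas_crossref(
        esnps, genotypes, catalog, threshold=cfg.ld.threshold,
        window_bp=cfg.ld.proxy_window_bp,
    )
    save(xref, "gwas_crossref.tsv")

    # -- direction reconciliation --------------------------------------------
    profiles = []
    for snp in cfg.profile_snps or [causal]:
        try:
            profiles.append(
                direction_profile(snp, measurements, genotypes, covariates, alpha=cfg.qtl.alpha)
            )
        except ValueError as exc:  # e.g. MAF failure on a requested SNP
            logger.warning("direction profile for %s skipped: %s", snp, exc)
    if profiles:
        save(pd.concat([p.to_frame() for p in profiles], ignore_index=True),
             "direction_report.tsv")
        digest = "\n\n".join(p.digest() for p in profiles)
        (out / "direction_report.txt").write_text(digest + "\n")
        artifacts["direction_report.txt"] = str(out / "direction_report.txt")

    summary = {
        "config": cfg.model_dump(),
        "seeds": seeds,
        "version": __version__,
        "n_snps": len(genotypes.snp_ids),
        "n_tests_eqtl": len(eqtl_results),
        "n_tests_spliceqtl": len(splice_results),
        "n_significant_esnps": len(esnps),
        "significant_esnps": esnps,
        "n_ld_blocks": len(block_set.blocks),
        "n_independent_signals": len(block_set.independent),
        "gwas_esnps_with_hit": xref_summary["n_esnps_with_hit"],
        "flip_flags": {p.snp_id: p.flip_flag for p in profiles},
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
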