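"""Readers and writers for the pipeline's on-disk formats.

All coordinates are 1-based inclusive (SAM POS / GFF3 convention; no
half-open conversion anywhere). Delimited outputs are tab-separated with a
single header line and a fixed float format so that re-running a seeded
pipeline reproduces byte-identical files.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .cohort import AlignedRead
from .models import GeneModel, GenotypeMatrix, SpliceVariant

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, *, index_label: Optional[str] = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index=index_label is not None, index_label=index_label)


def read_matrix_tsv(path, *, index_col: int = 0) -> pd.DataFrame:
    """Feature/sample matrix with the first column as index."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -- genotypes ---------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Dosage matrix: one row per SNP (metadata columns then samples)."""
    write_tsv(genotypes.to_frame(), path)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp_id", "chrom", "position", "ref", "alt", "maf"]
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        samples=samples,
        snps=df[meta_cols].copy(),
        dosages=df[samples].to_numpy(dtype=float).T,
    )


def write_vcf(genotypes: GenotypeMatrix, path, *, chrom_length: int = 51_000_000) -> None:
    """Uncompressed VCF with GT (hard-called from dosage) and DS fields."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(genotypes.snps["chrom"]):
        header.contigs.add(chrom, length=chrom_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DS", 1, "Float", "Alternate allele dosage")
    for s in genotypes.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, (_, snp) in enumerate(genotypes.snps.iterrows()):
            rec = vcf.new_record(
                contig=snp["chrom"],
                start=int(snp["position"]) - 1,
                stop=int(snp["position"]),
                alleles=(snp["ref"], snp["alt"]),
                id=snp["snp_id"],
            )
            for i, s in enumerate(genotypes.samples):
                ds = genotypes.dosages[i, j]
                if np.isnan(ds):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    n_alt = int(round(ds))
                    rec.samples[s]["GT"] = tuple([1] * n_alt + [0] * (2 - n_alt))
                    rec.samples[s]["DS"] = float(ds)
            vcf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages from a VCF, preferring DS over hard genotypes."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows, dosages = [], []
        for rec in vcf:
            rows.append(
                {
                    "snp_id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "maf": np.nan,
                }
            )
            col = []
            for s in samples:
                smp = rec.samples[s]
                ds = smp.get("DS")
                if ds is not None:
                    col.append(float(ds))
                else:
                    gt = smp.get("GT")
                    col.append(
                        np.nan if gt is None or None in gt else float(sum(gt))
                    )
            dosages.append(col)
    gm = GenotypeMatrix(
        samples=samples,
        snps=pd.DataFrame(rows),
        dosages=np.array(dosages, dtype=float).T,
    )
    gm.snps["maf"] = gm.empirical_maf()
    return gm


# -- gene models -------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Gene / mRNA / exon features; retained introns appear as merged exons
    of the corresponding transcript. Coding status is carried in biotype."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\tspliceqtl\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
            for v in g.variants:
                biotype = "protein_coding" if v.coding else "retained_intron"
                blocks = g.variant_blocks(v)
                fh.write(
                    f"{g.chrom}\tspliceqtl\tmRNA\t{blocks[0][0]}\t{blocks[-1][1]}\t.\t"
                    f"{g.strand}\t.\tID={v.variant_id};Parent={g.gene_id};biotype={biotype}\n"
                )
                for k, (s, e) in enumerate(blocks, 1):
                    fh.write(
                        f"{g.chrom}\tspliceqtl\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={v.variant_id}.exon{k};Parent={v.variant_id}\n"
                    )


def read_gff3(path) -> list[GeneModel]:
    """Reconstruct gene models (exons, variants, retained introns) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for tf in db.children(gf, featuretype="mRNA", order_by="start"):
            blocks = [
                (ex.start, ex.end)
                for ex in db.children(tf, featuretype="exon", order_by="start")
            ]
            coding = tf.attributes.get("biotype", [""])[0] == "protein_coding"
            transcripts.append((tf.id, coding, blocks))
        coding_tx = [t for t in transcripts if t[1]]
        if not coding_tx:
            raise ValueError(f"gene {gf.id} has no protein_coding transcript")
        exons = coding_tx[0][2]  # the coding transcript splices every intron
        introns = [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
        ]
        variants = []
        for tx_id, coding, blocks in transcripts:
            gaps = {(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(blocks, blocks[1:])}
            spliced = frozenset(
                (gf.strand, s, e) for (s, e) in introns if (s, e) in gaps
            )
            retained = frozenset(
                i for i, (s, e) in enumerate(introns) if (s, e) not in gaps
            )
            variants.append(SpliceVariant(tx_id, coding, spliced, retained))
        genes.append(GeneModel(gf.id, gf.seqid, gf.strand, exons, variants))
    return genes


# -- SAM ---------------------------------------------------------------------

def sam_header(chroms: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chroms.items()],
        }
    )


def write_sam(
    reads: Iterable[AlignedRead], path, *, chroms: dict[str, int]
) -> None:
    """Write alignment records as SAM text (with @SQ header, 1-based POS)."""
    header = sam_header(chroms)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.qname
            seg.flag = r.flag
            seg.reference_id = header.get_tid(r.chrom)
            seg.reference_start = r.pos - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = r.cigar
            fh.write(seg)


def write_sample_sams(
    read_stream: Iterable[tuple[str, list[AlignedRead]]],
    out_dir,
    *,
    chroms: dict[str, int],
) -> dict[str, Path]:
    """One SAM file per sample; returns sample -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, sample_reads in read_stream:
        p = out_dir / f"{sample}.sam"
        write_sam(sample_reads, p, chroms=chroms)
        paths[sample] = p
    return paths
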