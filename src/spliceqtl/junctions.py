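"""Splice-junction quantification from alignment records.

Junctions are identified by N operations in the CIGAR string: the N's
reference span is the intron, stored 1-based inclusive. Reference-consuming
operations are M, D, N, = and X; I, S and H consume no reference. Junctions
are grouped by (chrom, strand, intron_start, intron_end), annotated to the
host gene whose span contains the intron (smallest span wins on ties), and
normalized per sample for library size and gene-wise transcript abundance.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import AlignedRead
from .models import GeneModel, Junction

logger = logging.getLogger(__name__)

_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")
_ALLOWED_OPS = set("MIDNSH=X")
_REF_CONSUMING = set("MDN=X")


class CigarError(ValueError):
    """Malformed CIGAR string; the message names the offending token."""


@lru_cache(maxsize=200_000)
def parse_cigar(cigar: str) -> tuple[tuple[int, str], ...]:
    """Parse a CIGAR string into ((length, op), ...), validating ops."""
    if not cigar or cigar == "*":
        return ()
    ops = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR {cigar!r} at {cigar[pos:m.start()]!r}")
        length, op = int(m.group(1)), m.group(2)
        if op not in _ALLOWED_OPS:
            raise CigarError(f"unsupported CIGAR operation {m.group(0)!r} in {cigar!r}")
        if length <= 0:
            raise CigarError(f"non-positive length in CIGAR token {m.group(0)!r}")
        ops.append((length, op))
        pos = m.end()
    if pos != len(cigar):
        raise CigarError(f"malformed CIGAR {cigar!r} at {cigar[pos:]!r}")
    return tuple(ops)


def extract_junctions(
    read=None,
    *,
    pos: Optional[int] = None,
    cigar: Optional[str] = None,
    chrom: str = ".",
) -> list[Junction]:
    """One Junction per N operation of an alignment record.

    Accepts an :class:`~spliceqtl.cohort.AlignedRead`, a
    ``pysam.AlignedSegment``, or explicit ``pos``/``cigar`` keywords.
    Strand is unknown (``'.'``) at this stage. POS is 1-based; the junction
    covers the first through last reference base consumed by the N.
    """
    if read is not None:
        if hasattr(read, "cigarstring"):  # pysam.AlignedSegment
            pos = read.reference_start + 1
            cigar = read.cigarstring or "*"
            chrom = read.reference_name or "."
        else:
            pos, cigar, chrom = read.pos, read.cigar, read.chrom
    if pos is None or cigar is None:
        raise ValueError("extract_junctions needs a read or pos= and cigar=")
    if pos < 1:
        raise CigarError(f"POS must be >= 1, got {pos}")
    ref = pos
    out = []
    for length, op in parse_cigar(cigar):
        if op == "N":
            out.append(Junction(chrom, ".", ref, ref + length - 1))
        if op in _REF_CONSUMING:
            ref += length
    return out


def reference_span(pos: int, cigar: str) -> tuple[int, int]:
    """First and last reference base covered by an alignment (1-based)."""
    consumed = sum(l for l, op in parse_cigar(cigar) if op in _REF_CONSUMING)
    return pos, pos + max(consumed, 1) - 1


@dataclass
class JunctionCountMatrix:
    """Raw split-read counts per sample and junction.

    ``gene_read_counts`` holds per-sample total mapped reads overlapping each
    annotated gene's span -- the transcript-abundance proxy used by
    gene-wise normalization.
    """

    junctions: list[Junction]
    samples: list[str]
    raw_counts: pd.DataFrame           # samples x junction labels, ints
    library_sizes: pd.Series           # mapped reads per sample
    gene_read_counts: Optional[pd.DataFrame] = None  # samples x gene ids


@dataclass
class NormalizedJunctionMatrix:
    junctions: list[Junction]
    values: pd.DataFrame               # samples x junction labels


ReadSource = Union[str, Path, Iterable]


def _iter_reads(source: ReadSource):
    """Yield (chrom, pos, cigar, mapped, mapq) tuples from a SAM path or an
    iterable of AlignedRead / pysam.AlignedSegment."""
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            for seg in fh:
                yield (
                    seg.reference_name or ".",
                    (seg.reference_start or 0) + 1,
                    seg.cigarstring or "*",
                    not seg.is_unmapped,
                    seg.mapping_quality,
                )
    else:
        for r in source:
            if hasattr(r, "cigarstring"):
                yield (
                    r.reference_name or ".",
                    (r.reference_start or 0) + 1,
                    r.cigarstring or "*",
                    not r.is_unmapped,
                    r.mapping_quality,
                )
            else:
                yield r.chrom, r.pos, r.cigar, not r.is_unmapped, r.mapq


def assign_gene(
    chrom: str, start: int, end: int, genes: Sequence[GeneModel]
) -> Optional[GeneModel]:
    """Gene whose span contains [start, end] on `chrom`; smallest span wins.

    Ambiguities (interval contained in several overlapping genes) are
    resolved by the tie-break and logged.
    """
    hits = [
        g
        for g in genes
        if g.chrom == chrom and g.span[0] <= start and end <= g.span[1]
    ]
    if not hits:
        return None
    if len(hits) > 1:
        hits.sort(key=lambda g: (g.span[1] - g.span[0], g.gene_id))
        logger.warning(
            "interval %s:%d-%d contained in %d genes; assigned to %s (smallest span)",
            chrom, start, end, len(hits), hits[0].gene_id,
        )
        return hits[0]
    return hits[0]


def count_junctions(
    reads: Mapping[str, ReadSource],
    annotation: Sequence[GeneModel],
    *,
    min_mapq: int = 0,
) -> JunctionCountMatrix:
    """Count CIGAR N operations per sample and junction key.

    A read with k N operations contributes 1 to each of k junctions.
    Library size is the number of mapped reads per sample; per-gene read
    totals count mapped reads whose reference span overlaps the gene span.
    """
    genes = list(annotation)
    per_sample: dict[str, dict[tuple[str, int, int], int]] = {}
    lib: dict[str, int] = {}
    gene_reads: dict[str, dict[str, int]] = {}
    for sample, source in reads.items():
        counter: dict[tuple[str, int, int], int] = {}
        n_mapped = 0
        greads = {g.gene_id: 0 for g in genes}
        for chrom, pos, cigar, mapped, mapq in _iter_reads(source):
            if not mapped or cigar == "*" or mapq < min_mapq:
                continue
            n_mapped += 1
            for j in extract_junctions(pos=pos, cigar=cigar, chrom=chrom):
                k = (chrom, j.intron_start, j.intron_end)
                counter[k] = counter.get(k, 0) + 1
            rstart, rend = reference_span(pos, cigar)
            for g in genes:
                if g.chrom == chrom and rstart <= g.span[1] and rend >= g.span[0]:
                    greads[g.gene_id] += 1
        per_sample[sample] = counter
        lib[sample] = n_mapped
        gene_reads[sample] = greads

    keys = sorted({k for c in per_sample.values() for k in c})
    junctions = []
    for chrom, s, e in keys:
        g = assign_gene(chrom, s, e, genes)
        junctions.append(
            Junction(chrom, g.strand if g else ".", s, e, gene_id=g.gene_id if g else None)
        )
    samples = list(reads)
    counts = pd.DataFrame(
        [
            [per_sample[smp].get((j.chrom, j.intron_start, j.intron_end), 0) for j in junctions]
            for smp in samples
        ],
        index=samples,
        columns=[j.label for j in junctions],
        dtype=int,
    )
    return JunctionCountMatrix(
        junctions=junctions,
        samples=samples,
        raw_counts=counts,
        library_sizes=pd.Series(lib, name="library_size").loc[samples],
        gene_read_counts=pd.DataFrame(gene_reads).T.loc[samples]
        if genes
        else None,
    )


def normalize_junction_counts(
    counts: JunctionCountMatrix,
    *,
    eps: float = 1e-8,
) -> NormalizedJunctionMatrix:
    """Library-size and gene-wise transcript-abundance normalization.

    With L_i the library size of sample i and ``scaled = raw / (L_i /
    median(L))``, each junction value is divided by the sample's gene factor
    ``g_i = A_i / median_k(A_k)`` where A_i is the library-scaled read total
    over the junction's host gene (per-gene mapped reads when available,
    falling back to the gene's split-read total otherwise). ``eps`` guards
    genes with no reads anywhere; junctions without a host gene are dropped
    with a warning.
    """
    kept = [j for j in counts.junctions if j.gene_id is not None]
    dropped = [j.label for j in counts.junctions if j.gene_id is None]
    if dropped:
        logger.warning("dropping %d unannotated junctions: %s", len(dropped), dropped)

    libs = counts.library_sizes.astype(float)
    positive = libs[libs > 0]
    med_lib = float(positive.median()) if len(positive) else 1.0
    scale = (libs / med_lib).replace(0.0, np.nan)

    scaled = counts.raw_counts[[j.label for j in kept]].astype(float).div(scale, axis=0)

    values = scaled.copy()
    for gene_id in sorted({j.gene_id for j in kept}):
        jcols = [j.label for j in kept if j.gene_id == gene_id]
        if counts.gene_read_counts is not None and gene_id in counts.gene_read_counts:
            totals = counts.gene_read_counts[gene_id].astype(float).div(scale)
        else:
            totals = scaled[jcols].sum(axis=1)
        med_tot = float(totals.median())
        if med_tot <= 0:
            logger.warning("gene %s has no reads in any sample; junctions set to 0", gene_id)
            values[jcols] = 0.0
            continue
        g = (totals / med_tot).clip(lower=eps)
        values[jcols] = scaled[jcols].div(g, axis=0)
    values = values.fillna(0.0)
    return NormalizedJunctionMatrix(junctions=kept, values=values)
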