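"""Linkage-disequilibrium blocks, proxy lookup and GWAS cross-reference.

LD r^2 is the squared Pearson correlation of alternate-allele dosages over
pairwise-complete samples (composite LD; no haplotype phasing). Significant
SNPs are clustered greedily by significance rank: the most significant
unassigned SNP seeds a block and captures every unassigned SNP with
r^2 > threshold; blocks that capture nobody are independent signals.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import GenotypeMatrix, LdBlock, LdBlockSet

logger = logging.getLogger(__name__)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Requires >= 3 pairwise-complete samples and both SNPs polymorphic;
    returns NaN otherwise (LD undefined for a monomorphic SNP).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) ** 2 / ((a @ a) * (b @ b)))


def _rank_order(
    snps: Sequence[str], genotypes: GenotypeMatrix, meta_p: Optional[dict[str, float]]
) -> list[str]:
    """Significance order (ascending meta p), position as tie-break."""
    def sort_key(s: str):
        pos = int(genotypes.snp_info(s)["position"])
        p = meta_p.get(s, np.inf) if meta_p else np.inf
        return (p, pos)

    return sorted(snps, key=sort_key)


def cluster_ld_blocks(
    snps: Sequence[str],
    genotypes: GenotypeMatrix,
    threshold: float = 0.8,
    *,
    meta_p: Optional[dict[str, float]] = None,
) -> LdBlockSet:
    """Greedy partition of SNPs into LD blocks (r^2 > threshold, strict).

    ``snps`` may be pre-ranked (most significant first); passing ``meta_p``
    re-ranks by ascending p with genomic position breaking ties. Singleton
    blocks are reported as independent signals. Blocks and independents
    partition the input exactly.
    """
    for s in snps:
        genotypes.index_of(s)  # raises naming the missing SNP
    order = _rank_order(snps, genotypes, meta_p) if meta_p is not None else list(snps)
    unassigned = list(order)
    blocks: list[LdBlock] = []
    independent: list[str] = []
    while unassigned:
        rep = unassigned.pop(0)
        rep_d = genotypes.dosage_of(rep)
        members, r2s = [], {}
        rest = []
        for s in unassigned:
            r2 = ld_r2(rep_d, genotypes.dosage_of(s))
            if np.isfinite(r2) and r2 > threshold:
                members.append(s)
                r2s[s] = r2
            else:
                rest.append(s)
        unassigned = rest
        if members:
            blocks.append(LdBlock(representative=rep, members=members, member_r2=r2s))
        else:
            independent.append(rep)
    return LdBlockSet(blocks=blocks, independent=independent)


def find_proxies(
    query: str,
    genotypes: GenotypeMatrix,
    threshold: float = 0.8,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """SNPs within ``window_bp`` of the query with r^2 >= threshold.

    Sorted by r^2 descending; the query itself is excluded. Note proxy
    lookup uses >= (the LDproxy convention) while block clustering uses a
    strict >.
    """
    info = genotypes.snp_info(query)
    qd = genotypes.dosage_of(query)
    rows = []
    for s in genotypes.snp_ids:
        if s == query:
            continue
        si = genotypes.snp_info(s)
        if si["chrom"] != info["chrom"] or abs(int(si["position"]) - int(info["position"])) > window_bp:
            continue
        r2 = ld_r2(qd, genotypes.dosage_of(s))
        if np.isfinite(r2) and r2 >= threshold:
            rows.append({"snp_id": s, "r2": r2, "position": int(si["position"])})
    df = pd.DataFrame(rows, columns=["snp_id", "r2", "position"])
    return df.sort_values(["r2", "snp_id"], ascending=[False, True]).reset_index(drop=True)


def read_gwas_catalog(path) -> pd.DataFrame:
    """Load a GWAS-catalog extract (TSV: snp_id, trait, study)."""
    cat = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "trait", "study"}
    missing = required - set(cat.columns)
    if missing:
        raise ValueError(f"GWAS catalog missing columns: {sorted(missing)}")
    return cat.drop_duplicates(subset=["snp_id", "trait"]).reset_index(drop=True)


def gwas_crossref(
    esnps: Sequence[str],
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    threshold: float = 0.8,
    window_bp: int = 500_000,
) -> tuple[pd.DataFrame, dict]:
    """Cross-reference eSNPs (and their LD proxies) against a GWAS catalog.

    For each eSNP the report lists direct hits (the SNP itself appears in
    the catalog) and proxy hits (a proxy at r^2 >= threshold appears), each
    with trait, study and r^2. The summary counts eSNPs with any hit.
    """
    cat_by_snp: dict[str, list] = {}
    for _, row in catalog.iterrows():
        cat_by_snp.setdefault(row["snp_id"], []).append(row)
    rows = []
    n_hit = 0
    for snp in esnps:
        any_hit = False
        for row in cat_by_snp.get(snp, []):
            rows.append(
                {"esnp": snp, "hit_type": "direct", "hit_snp": snp,
                 "r2": 1.0, "trait": row["trait"], "study": row["study"]}
            )
            any_hit = True
        proxies = find_proxies(snp, genotypes, threshold=threshold, window_bp=window_bp)
        for _, prox in proxies.iterrows():
            for row in cat_by_snp.get(prox["snp_id"], []):
                rows.append(
                    {"esnp": snp, "hit_type": "proxy", "hit_snp": prox["snp_id"],
                     "r2": float(prox["r2"]), "trait": row["trait"], "study": row["study"]}
                )
                any_hit = True
        n_hit += any_hit
    report = pd.DataFrame(
        rows, columns=["esnp", "hit_type", "hit_snp", "r2", "trait", "study"]
    )
    summary = {"n_esnps": len(list(esnps)), "n_esnps_with_hit": int(n_hit)}
    return report, summary
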