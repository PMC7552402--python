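"""Cis-eQTL / cis-spliceQTL association engine.

Per cohort, each feature is regressed on alternate-allele dosage with age,
sex and smoking as covariates (ordinary least squares, two-sided t test).
SNPs are restricted to a cis window of +/- 1 Mb around the feature anchor
(boundary inclusive) and filtered at MAF < 0.05 (strict). Cohorts are
combined by inverse-variance-weighted fixed effects, then Bonferroni and
Benjamini-Hochberg multiplicity adjustments are applied over the family of
all tested SNP-feature pairs.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GenotypeMatrix, MetaQtlResult, QtlResult

logger = logging.getLogger(__name__)


def select_cis_snps(
    feature_anchor: tuple[str, int],
    snps: pd.DataFrame,
    *,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """SNPs within ``window_bp`` of the anchor on the same chromosome.

    The window boundary is inclusive on both sides.
    """
    chrom, position = feature_anchor
    mask = (snps["chrom"] == chrom) & (
        (snps["position"] - position).abs() <= window_bp
    )
    return snps[mask]


def filter_maf(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Remove SNPs with sample MAF strictly below ``threshold``.

    MAF is computed from mean dosage / 2, folded at 0.5; SNPs at exactly the
    threshold are kept.
    """
    maf = genotypes.empirical_maf()
    keep = [s for s, m in zip(genotypes.snp_ids, maf) if m >= threshold]
    return genotypes.subset(keep)


def _genotype_high(beta: float, ref: str, alt: str) -> str:
    return f"{alt}{alt}" if beta > 0 else f"{ref}{ref}"


def fit_qtl(
    feature_values: np.ndarray,
    dosage: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    *,
    snp_id: str = "snp",
    feature_id: str = "feature",
    cohort: Optional[str] = None,
    ref: str = "A",
    alt: str = "B",
) -> QtlResult:
    """OLS fit of feature ~ dosage + covariates; dosage beta, se and t-test p.

    Rows with any missing value are dropped pairwise. The result is flagged
    untestable when fewer than (number of covariates + 3) complete samples
    remain or the dosage does not vary. ``genotype_high_expression`` is the
    alt homozygote when beta > 0, the ref homozygote otherwise.
    """
    y = np.asarray(feature_values, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ok = np.isfinite(y) & np.isfinite(d) & np.all(np.isfinite(C), axis=1)
    y, d, C = y[ok], d[ok], C[ok]
    n = len(y)
    n_cov = C.shape[1]
    untestable = QtlResult(
        snp_id=snp_id, feature_id=feature_id, beta=np.nan, se=np.nan,
        p_value=np.nan, n=n, cohort=cohort, testable=False,
    )
    if n < n_cov + 3 or np.ptp(d) == 0:
        return untestable
    X = np.column_stack([np.ones(n), d, C])
    p = X.shape[1]
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return untestable
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    df = n - p
    if df <= 0:
        return untestable
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0)))
    beta = float(beta_hat[1])
    if se == 0:
        pval = 0.0 if beta != 0 else 1.0
    else:
        pval = float(2 * stats.t.sf(abs(beta / se), df))
    pval = min(max(pval, np.finfo(float).tiny), 1.0)
    return QtlResult(
        snp_id=snp_id,
        feature_id=feature_id,
        beta=beta,
        se=se,
        p_value=pval,
        n=n,
        cohort=cohort,
        genotype_high_expression=_genotype_high(beta, ref, alt),
        testable=True,
    )


def meta_qtl(per_cohort: Sequence[QtlResult], *, ref: str = "A", alt: str = "B") -> MetaQtlResult:
    """Inverse-variance-weighted fixed-effect combination across cohorts.

    meta_beta = sum(w_c * beta_c) / sum(w_c) with w_c = 1 / se_c^2;
    meta_se = sum(w_c) ** -0.5; two-sided Wald p.
    """
    if not per_cohort:
        raise ValueError("meta_qtl needs at least one cohort result")
    usable = [r for r in per_cohort if r.testable and np.isfinite(r.se) and r.se > 0]
    snp_id = per_cohort[0].snp_id
    feature_id = per_cohort[0].feature_id
    if not usable:
        return MetaQtlResult(
            snp_id=snp_id, feature_id=feature_id, meta_beta=np.nan, meta_se=np.nan,
            meta_p=np.nan, n_total=sum(r.n for r in per_cohort),
            per_cohort=list(per_cohort), testable=False,
        )
    w = np.array([1.0 / r.se**2 for r in usable])
    betas = np.array([r.beta for r in usable])
    meta_beta = float((w * betas).sum() / w.sum())
    meta_se = float(w.sum() ** -0.5)
    z = meta_beta / meta_se
    meta_p = min(max(float(2 * stats.norm.sf(abs(z))), np.finfo(float).tiny), 1.0)
    return MetaQtlResult(
        snp_id=snp_id,
        feature_id=feature_id,
        meta_beta=meta_beta,
        meta_se=meta_se,
        meta_p=meta_p,
        n_total=sum(r.n for r in usable),
        per_cohort=list(per_cohort),
        genotype_high_expression=_genotype_high(meta_beta, ref, alt),
        testable=True,
    )


def adjust_multiplicity(
    results: Sequence[MetaQtlResult],
    *,
    alpha: float = 0.05,
    family: str = "global",
) -> list[MetaQtlResult]:
    """Fill bonferroni_p, BH fdr and the significance flag in place.

    ``family`` is "global" (all tested SNP-feature pairs in the run, the
    default) or "per_feature". Untestable results are left unadjusted.
    """
    if not results:
        raise ValueError("adjust_multiplicity needs a non-empty result list")
    if family == "global":
        groups = {"_all": [r for r in results if r.testable]}
    elif family == "per_feature":
        groups = {}
        for r in results:
            if r.testable:
                groups.setdefault(r.feature_id, []).append(r)
    else:
        raise ValueError(f"unknown family {family!r}")
    for members in groups.values():
        if not members:
            continue
        m = len(members)
        pvals = np.array([r.meta_p for r in members])
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(members, fdr):
            r.bonferroni_p = float(min(1.0, m * r.meta_p))
            r.fdr = float(q)
            r.significant = bool(r.bonferroni_p < alpha)
    return list(results)


def map_cis_qtl(
    expr: pd.DataFrame,
    anchors: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    *,
    window_bp: int = 1_000_000,
    maf: float = 0.05,
    alpha: float = 0.05,
    family: str = "global",
    smoking_mode: str = "current",
) -> tuple[list[MetaQtlResult], pd.DataFrame]:
    """Full cis scan: window selection, MAF filter, per-cohort OLS, meta.

    ``expr`` is samples x features (taken as-is: the caller chooses the
    transform); ``anchors`` has columns feature_id, chrom, position;
    ``covariates`` must include cohort, age, sex and smoking columns.
    Returns the MetaQtlResult list and a tidy results table.
    """
    from .expression import adjustment_design

    cov = covariates.set_index("sample_id").loc[list(expr.index)].reset_index()
    design = adjustment_design(cov, smoking_mode=smoking_mode)
    design = design.loc[list(expr.index), ["age", "sex_male", "smoking_current"]]
    filtered = filter_maf(genotypes, maf)
    sample_pos = {s: i for i, s in enumerate(filtered.samples)}
    idx = [sample_pos[s] for s in expr.index]
    cohort_of = cov.set_index("sample_id")["cohort"]

    results: list[MetaQtlResult] = []
    for _, a in anchors.iterrows():
        cis = select_cis_snps((a["chrom"], int(a["position"])), filtered.snps, window_bp=window_bp)
        for _, snp in cis.iterrows():
            dos = filtered.dosages[:, filtered.index_of(snp["snp_id"])][idx]
            per_cohort = []
            for cname in sorted(cohort_of.unique()):
                mask = (cohort_of.loc[expr.index] == cname).to_numpy()
                per_cohort.append(
                    fit_qtl(
                        expr[a["feature_id"]].to_numpy()[mask],
                        dos[mask],
                        design.to_numpy()[mask],
                        snp_id=snp["snp_id"],
                        feature_id=a["feature_id"],
                        cohort=cname,
                        ref=snp["ref"],
                        alt=snp["alt"],
                    )
                )
            results.append(meta_qtl(per_cohort, ref=snp["ref"], alt=snp["alt"]))
    if results:
        adjust_multiplicity(results, alpha=alpha, family=family)
    return results, results_table(results)


def results_table(results: Sequence[MetaQtlResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "snp_id": r.snp_id,
            "feature_id": r.feature_id,
            "meta_beta": r.meta_beta,
            "meta_se": r.meta_se,
            "meta_p": r.meta_p,
            "n": r.n_total,
            "genotype_high_expression": r.genotype_high_expression,
            "bonferroni_p": r.bonferroni_p,
            "fdr": r.fdr,
            "significant": r.significant,
            "testable": r.testable,
        }
        for c in r.per_cohort:
            tag = c.cohort or "cohort"
            row[f"beta_{tag}"] = c.beta
            row[f"se_{tag}"] = c.se
            row[f"p_{tag}"] = c.p_value
        rows.append(row)
    return pd.DataFrame(rows)
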