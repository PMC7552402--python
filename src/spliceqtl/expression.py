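"""Cohort definition, covariate adjustment and differential expression.

The analysis cohort is defined spirometrically: COPD is FEV1/FVC < 70%,
non-COPD is >= 70%; subjects aged <= 40 years, with < 5 pack-years, never
smokers, or with other lung disease are excluded. Expression (log2
intensity, FPKM or normalized junction units) is adjusted for age, sex and
smoking with a Huber M-estimator robust linear model; group differences use
the Mann-Whitney U test and lung-function correlations use Spearman's rho.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import ConfigurationError, validate_covariates

logger = logging.getLogger(__name__)

HUBER_T = 1.345

_REQUIRED_FOR_CLASSIFICATION = [
    "age", "pack_years", "smoking", "fev1_fvc_ratio", "other_lung_disease",
]


def classify_cohort(covariates: pd.DataFrame) -> pd.DataFrame:
    """Label each sample COPD / non-COPD / excluded (with a reason).

    Inclusion requires age > 40 (strict), >= 5 pack-years, and current or
    ex-smoking; other lung disease excludes. Among included samples, COPD
    iff FEV1/FVC < 70, non-COPD iff >= 70 (boundary inclusive).
    """
    validate_covariates(covariates)
    labels, reasons = [], []
    for _, row in covariates.iterrows():
        missing = [c for c in _REQUIRED_FOR_CLASSIFICATION if pd.isna(row.get(c))]
        if missing:
            labels.append("excluded")
            reasons.append(f"missing:{','.join(missing)}")
            logger.warning("sample %s excluded, missing %s", row["sample_id"], missing)
            continue
        if row["age"] <= 40:
            labels.append("excluded"); reasons.append("age<=40"); continue
        if row["pack_years"] < 5:
            labels.append("excluded"); reasons.append("pack_years<5"); continue
        if row["smoking"] == "never":
            labels.append("excluded"); reasons.append("never_smoker"); continue
        if bool(row["other_lung_disease"]):
            labels.append("excluded"); reasons.append("other_lung_disease"); continue
        if row["fev1_fvc_ratio"] < 70:
            labels.append("COPD"); reasons.append("")
        else:
            labels.append("non-COPD"); reasons.append("")
    return pd.DataFrame(
        {"sample_id": covariates["sample_id"].to_numpy(), "label": labels, "reason": reasons}
    ).set_index("sample_id")


def adjustment_design(
    covariates: pd.DataFrame, *, smoking_mode: str = "current_vs_ex"
) -> pd.DataFrame:
    """Design matrix (intercept, age, sex, smoking indicator) per sample.

    ``smoking_mode`` names the indicator: "current_vs_ex" encodes current=1
    within a current/ex cohort; "current" is the same indicator read as
    current-smoking status (never smokers, if present, also code 0).
    """
    cov = covariates.set_index("sample_id")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "age": cov["age"].astype(float),
            "sex_male": (cov["sex"] == "male").astype(float),
            "smoking_current": (cov["smoking"] == "current").astype(float),
        },
        index=cov.index,
    )
    return X


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    keep = ["const"]
    for col in X.columns:
        if col == "const":
            continue
        candidate = X[keep + [col]]
        if np.linalg.matrix_rank(candidate.to_numpy()) == len(keep) + 1:
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear adjustment term {col!r}", stacklevel=2)
    return X[keep]


def adjust_expression(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    smoking_mode: str = "current_vs_ex",
) -> pd.DataFrame:
    """Robust (Huber) covariate adjustment, feature by feature.

    Returns residual + fitted intercept so adjusted values stay on the
    original scale. ``expr`` is samples x features.
    """
    X = adjustment_design(covariates, smoking_mode=smoking_mode)
    common = [s for s in expr.index if s in X.index]
    if not common:
        raise ConfigurationError("no overlap between expression samples and covariates")
    X = _drop_collinear(X.loc[common])
    out = pd.DataFrame(index=common, columns=expr.columns, dtype=float)
    for feature in expr.columns:
        y = expr.loc[common, feature].astype(float)
        if not np.isfinite(y).all():
            raise ConfigurationError(f"non-finite expression values for {feature!r}")
        model = sm.RLM(y.to_numpy(), X.to_numpy(), M=sm.robust.norms.HuberT(t=HUBER_T))
        fit = model.fit(maxiter=200, tol=1e-10, conv="coefs")
        out[feature] = y.to_numpy() - X.to_numpy() @ fit.params + fit.params[0]
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first group).

    Exact null distribution when both groups have <= 8 observations and the
    pooled data are tie-free; normal approximation with tie correction and
    continuity correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    adjusted: pd.DataFrame,
    labels: pd.DataFrame,
    *,
    gold_stage: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """COPD vs non-COPD Mann-Whitney per feature; optionally per GOLD stage.

    ``labels`` comes from :func:`classify_cohort`. When ``gold_stage`` is
    given, each stage is additionally compared against the non-COPD group.
    """
    lab = labels.loc[[s for s in adjusted.index if s in labels.index], "label"]
    copd = lab[lab == "COPD"].index
    ctrl = lab[lab == "non-COPD"].index
    rows = []
    comparisons = [("COPD_vs_nonCOPD", copd)]
    if gold_stage is not None:
        for stage in sorted(set(gold_stage.loc[copd].astype(str)) - {"none"}):
            comparisons.append(
                (f"GOLD{stage}_vs_nonCOPD", gold_stage.loc[copd][gold_stage.loc[copd].astype(str) == stage].index)
            )
    for feature in adjusted.columns:
        for name, grp in comparisons:
            if len(grp) == 0 or len(ctrl) == 0:
                logger.warning("comparison %s for %s skipped: empty group", name, feature)
                continue
            xs = adjusted.loc[grp, feature].to_numpy()
            ys = adjusted.loc[ctrl, feature].to_numpy()
            u, p = mann_whitney_u(xs, ys)
            rows.append(
                {
                    "feature": feature,
                    "comparison": name,
                    "n_group": len(xs),
                    "n_control": len(ys),
                    "median_group": float(np.median(xs)),
                    "median_control": float(np.median(ys)),
                    "U": u,
                    "p_value": p,
                    "adjusted_for": "age,sex,smoking",
                }
            )
    return pd.DataFrame(rows)


def correlate_lung_function(
    adjusted: pd.DataFrame,
    covariates: pd.DataFrame,
    labels: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Spearman correlation of each feature with FEV1 %pred and FEV1/FVC.

    Reported overall and, when labels are given, within COPD and non-COPD
    separately. Constant inputs yield a missing rho.
    """
    cov = covariates.set_index("sample_id")
    groups = {"all": list(adjusted.index)}
    if labels is not None:
        lab = labels["label"]
        groups["COPD"] = [s for s in adjusted.index if lab.get(s) == "COPD"]
        groups["non-COPD"] = [s for s in adjusted.index if lab.get(s) == "non-COPD"]
    rows = []
    for feature in adjusted.columns:
        for measure in ("fev1_pct_pred", "fev1_fvc_ratio"):
            for gname, members in groups.items():
                members = [s for s in members if s in cov.index]
                if len(members) < 3:
                    continue
                x = adjusted.loc[members, feature].to_numpy(dtype=float)
                y = cov.loc[members, measure].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = stats.spearmanr(x, y)
                rows.append(
                    {
                        "feature": feature,
                        "measure": measure,
                        "group": gname,
                        "rho": rho,
                        "p_value": p,
                        "n": len(members),
                    }
                )
    return pd.DataFrame(rows)
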