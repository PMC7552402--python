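"""Cohort classification, robust adjustment, Mann-Whitney and Spearman."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spliceqtl as sq
from spliceqtl.expression import adjustment_design, mann_whitney_u


def cov_row(sample_id="S1", age=64.0, sex="male", smoking="ex", pack_years=41.5,
            fev1=62.17, ratio=58.33, gold="2", old=False):
    return {
        "sample_id": sample_id, "cohort": "c1", "age": age, "sex": sex,
        "smoking": smoking, "pack_years": pack_years, "fev1_pct_pred": fev1,
        "fev1_fvc_ratio": ratio, "gold_stage": gold, "other_lung_disease": old,
    }


def exact_mw_p(x, y):
    """Exhaustive enumeration of all rank arrangements (two-sided).

    Independent oracle: assigns the pooled ranks to every possible group-1
    subset and measures the extremity of U around its null mean.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    mu = n1 * n2 / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n1 + n2), n1)])
    p = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-9)
    return u_obs, min(float(p), 1.0)


class TestClassifyCohort:
    def test_table1_like_copd_case(self):
        cov = pd.DataFrame([cov_row()])  # median COPD subject profile
        lab = sq.classify_cohort(cov)
        assert lab.loc["S1", "label"] == "COPD"

    def test_ratio_70_boundary_is_non_copd(self):
        cov = pd.DataFrame([cov_row(ratio=70.0, age=62, smoking="current",
                                    pack_years=38, gold="none")])
        assert sq.classify_cohort(cov).loc["S1", "label"] == "non-COPD"

    @pytest.mark.parametrize(
        "row,reason",
        [
            (cov_row(age=35.0, ratio=55.0), "age<=40"),
            (cov_row(age=40.0), "age<=40"),            # strict > 40
            (cov_row(pack_years=4.0), "pack_years<5"),
            (cov_row(smoking="never"), "never_smoker"),
            (cov_row(old=True), "other_lung_disease"),
        ],
    )
    def test_exclusions_with_reasons(self, row, reason):
        lab = sq.classify_cohort(pd.DataFrame([row]))
        assert lab.loc["S1", "label"] == "excluded"
        assert lab.loc["S1", "reason"] == reason

    def test_missing_field_excluded_with_reason(self):
        row = cov_row()
        row["pack_years"] = np.nan
        lab = sq.classify_cohort(pd.DataFrame([row]))
        assert lab.loc["S1", "label"] == "excluded"
        assert "pack_years" in lab.loc["S1", "reason"]

    def test_every_sample_gets_exactly_one_label(self):
        cov = sq.simulate_cohort(100, 40, seed=3)
        cov.loc[3, "age"] = 39.0
        cov.loc[5, "smoking"] = "never"
        lab = sq.classify_cohort(cov)
        assert len(lab) == 100
        assert set(lab["label"]) <= {"COPD", "non-COPD", "excluded"}
        assert (lab.loc[lab["label"] == "excluded", "reason"] != "").all()


def _adjust_fixture(seed=0, n=20):
    rng = np.random.default_rng(4)
    cov = pd.DataFrame([
        cov_row(sample_id=f"S{i}", age=float(a), sex=s, smoking=m,
                ratio=75.0, gold="none")
        for i, (a, s, m) in enumerate(zip(
            rng.uniform(45, 75, n).round(1),
            rng.choice(["male", "female"], n),
            rng.choice(["current", "ex"], n),
        ))
    ])
    X = adjustment_design(cov).to_numpy()
    return cov, X


class TestAdjustExpression:
    def test_perfectly_linear_in_age_collapses_to_intercept(self):
        cov, X = _adjust_fixture()
        y = 2.0 + 0.05 * X[:, 1]
        adj = sq.adjust_expression(pd.DataFrame({"f": y}, index=cov.sample_id), cov)
        np.testing.assert_allclose(adj["f"], 2.0, atol=1e-10)

    def test_huber_equals_ols_without_outliers(self):
        cov, X = _adjust_fixture()
        beta = np.array([5.0, 0.02, 0.3, -0.2])
        # noise orthogonal to the design, so OLS residuals equal it exactly;
        # all residuals inside the Huber threshold => no downweighting
        rng = np.random.default_rng(0)
        e = rng.uniform(-0.01, 0.01, len(X))
        P = X @ np.linalg.inv(X.T @ X) @ X.T
        e = e - P @ e
        import statsmodels.api as sm
        assert np.abs(e).max() < 1.345 * sm.robust.scale.mad(e)  # premise
        y = X @ beta + e
        adj = sq.adjust_expression(pd.DataFrame({"f": y}, index=cov.sample_id), cov)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(adj["f"], y - X @ ols + ols[0], atol=1e-6)

    def test_orthogonal_covariates_leave_values_unchanged(self):
        cov, X = _adjust_fixture()
        rng = np.random.default_rng(0)
        y = rng.uniform(-0.01, 0.01, len(X))
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]  # orthogonalize
        y = y + 3.0  # slopes exactly zero; values inside the Huber threshold
        adj = sq.adjust_expression(pd.DataFrame({"f": y}, index=cov.sample_id), cov)
        np.testing.assert_allclose(adj["f"], y, atol=1e-6)

    def test_adjustment_idempotent(self):
        cov, X = _adjust_fixture()
        rng = np.random.default_rng(2)
        y = X @ np.array([4.0, 0.03, -0.5, 0.4]) + rng.normal(0, 0.5, len(X))
        expr = pd.DataFrame({"f": y}, index=cov.sample_id)
        once = sq.adjust_expression(expr, cov)
        twice = sq.adjust_expression(once, cov)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-8

    def test_collinear_term_dropped_with_warning(self):
        cov, _ = _adjust_fixture()
        cov["sex"] = "male"  # single sex: indicator collinear with intercept
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(cov))
        with pytest.warns(UserWarning, match="collinear"):
            adj = sq.adjust_expression(
                pd.DataFrame({"f": y}, index=cov.sample_id), cov
            )
        assert np.isfinite(adj.to_numpy()).all()


class TestMannWhitney:
    def test_worked_example_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n1, n2 = rng.integers(1, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u_impl, p_impl = mann_whitney_u(x, y)
            u_oracle, p_oracle = exact_mw_p(x, y)
            assert u_impl == pytest.approx(u_oracle)
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_planted_copd_shift_detected(self, gene):
        """Planted disease effect on the coding variant is significant in
        every seed at n = 200 per group with modest noise."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            g = sq.simulate_genotypes(400, [(1, 0.3, 0.0)], 0, seed=1000 + seed)
            cov = sq.simulate_cohort(400, 200, seed=2000 + seed)
            spec = sq.EffectSpec(
                baseline={"V1": 10.0, "V2": 10.0, "V3": 10.0},
                disease_shift={"V1": 0.5}, noise_sd=0.2,
            )
            ab = sq.simulate_variant_abundances(g, cov, gene, spec, seed=3000 + seed)
            ms = sq.render_measurements(ab, gene, sq.probe_junction_of(gene),
                                        0.1, seed=4000 + seed)
            labels = sq.classify_cohort(cov)
            adj = sq.adjust_expression(ms.probe_log2.to_frame(), cov)
            res = sq.compare_groups(adj, labels)
            hits += res["p_value"].iloc[0] < 0.05
        assert hits >= 0.95 * n_seeds

    def test_gold_stage_breakdown_emitted(self):
        cov = sq.simulate_cohort(120, 60, seed=7)
        rng = np.random.default_rng(8)
        expr = pd.DataFrame({"f": rng.normal(size=120)}, index=cov.sample_id)
        labels = sq.classify_cohort(cov)
        gold = cov.set_index("sample_id")["gold_stage"]
        res = sq.compare_groups(expr, labels, gold_stage=gold)
        assert "COPD_vs_nonCOPD" in set(res["comparison"])
        assert any(c.startswith("GOLD") for c in res["comparison"])


class TestSpearman:
    def test_monotone_pairs(self):
        cov = pd.DataFrame([
            cov_row(sample_id=f"S{i}", ratio=float(r), fev1=float(f), gold="none")
            for i, (r, f) in enumerate([(71, 80), (75, 90), (80, 95), (85, 99), (90, 110)])
        ])
        expr = pd.DataFrame(
            {"up": [1.0, 2, 3, 4, 5], "down": [5.0, 4, 3, 2, 1]},
            index=cov.sample_id,
        )
        res = sq.correlate_lung_function(expr, cov)
        r_up = res[(res.feature == "up") & (res.measure == "fev1_fvc_ratio")]
        r_down = res[(res.feature == "down") & (res.measure == "fev1_fvc_ratio")]
        assert r_up["rho"].iloc[0] == pytest.approx(1.0)
        assert r_down["rho"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # ranks (1..5) vs (3,1,2,5,4): rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.6
        cov = pd.DataFrame([
            cov_row(sample_id=f"S{i}", ratio=float(r), gold="none")
            for i, r in enumerate([71, 72, 73, 74, 75])
        ])
        expr = pd.DataFrame({"f": [3.0, 1, 2, 5, 4]}, index=cov.sample_id)
        res = sq.correlate_lung_function(expr, cov)
        rho = res[(res.measure == "fev1_fvc_ratio")]["rho"].iloc[0]
        assert rho == pytest.approx(0.6)

    def test_constant_input_reported_missing(self):
        cov = pd.DataFrame([
            cov_row(sample_id=f"S{i}", ratio=float(70 + i), gold="none")
            for i in range(4)
        ])
        expr = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]}, index=cov.sample_id)
        res = sq.correlate_lung_function(expr, cov)
        assert res["rho"].isna().all()
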