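"""Synthetic cohort generator: calibration and planted-structure checks."""
import numpy as np
import pandas as pd
import pytest

import spliceqtl as sq
from spliceqtl.models import ConfigurationError, InvalidParameterError


class TestSimulateGenotypes:
    def test_seeded_determinism(self):
        a = sq.simulate_genotypes(200, [(4, 0.3, 0.9)], 3, seed=7)
        b = sq.simulate_genotypes(200, [(4, 0.3, 0.9)], 3, seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snps.equals(b.snps)

    def test_hardy_weinberg_frequencies(self):
        # maf 0.5: expected genotype proportions 0.25 / 0.50 / 0.25
        n = 10_000
        g = sq.simulate_genotypes(n, [(1, 0.5, 0.0)], 0, seed=42)
        d = g.dosages[:, 0]
        for dosage, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            count = int((d == dosage).sum())
            sd = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 3 * sd

    def test_perfect_block_gives_identical_haplotypes(self):
        g = sq.simulate_genotypes(300, [(5, 0.3, 1.0)], 0, seed=3)
        for j in range(1, 5):
            assert sq.ld_r2(g.dosages[:, 0], g.dosages[:, j]) == pytest.approx(1.0)

    def test_block_r2_near_requested(self):
        g = sq.simulate_genotypes(4000, [(4, 0.3, 0.9)], 0, seed=9)
        r2s = [sq.ld_r2(g.dosages[:, i], g.dosages[:, j])
               for i in range(4) for j in range(i + 1, 4)]
        assert np.mean(r2s) == pytest.approx(0.9, abs=0.05)

    def test_independent_snps_uncorrelated(self):
        g = sq.simulate_genotypes(4000, [], 5, seed=10)
        for i in range(5):
            for j in range(i + 1, 5):
                assert sq.ld_r2(g.dosages[:, i], g.dosages[:, j]) < 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 1, "block_spec": [(2, 0.3, 0.9)]},
            {"n_samples": 100, "block_spec": [(2, 0.0, 0.9)]},
            {"n_samples": 100, "block_spec": [(2, 0.6, 0.9)]},
            {"n_samples": 100, "block_spec": [(0, 0.3, 0.9)]},
            {"n_samples": 100, "block_spec": [(2, 0.3, 1.5)]},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            sq.simulate_genotypes(seed=1, **kwargs)


class TestSimulateCohort:
    def test_copd_count_and_ratio_boundaries(self):
        cov = sq.simulate_cohort(100, 40, seed=5)
        assert (cov["fev1_fvc_ratio"] < 70).sum() == 40
        assert (cov["fev1_fvc_ratio"] >= 70).sum() == 60

    def test_non_copd_gold_is_none(self):
        cov = sq.simulate_cohort(120, 50, seed=6)
        assert (cov.loc[cov["fev1_fvc_ratio"] >= 70, "gold_stage"] == "none").all()
        assert (cov.loc[cov["fev1_fvc_ratio"] < 70, "gold_stage"] != "none").all()

    def test_seeded_determinism(self):
        a = sq.simulate_cohort(80, 30, seed=8)
        b = sq.simulate_cohort(80, 30, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_all_samples_pass_inclusion_filters(self):
        cov = sq.simulate_cohort(150, 60, seed=9)
        labels = sq.classify_cohort(cov)
        assert (labels["label"] != "excluded").all()

    def test_too_many_cases_rejected(self):
        with pytest.raises(InvalidParameterError):
            sq.simulate_cohort(10, 11, seed=1)


class TestVariantAbundances:
    def test_null_model_returns_baselines(self, gene):
        g = sq.simulate_genotypes(10, [(1, 0.3, 0.0)], 0, seed=1)
        cov = sq.simulate_cohort(10, 0, seed=2)
        spec = sq.EffectSpec(baseline={"V1": 10.0, "V2": 20.0, "V3": 5.0}, noise_sd=0.0)
        ab = sq.simulate_variant_abundances(g, cov, gene, spec, seed=3)
        for v, b in spec.baseline.items():
            np.testing.assert_allclose(ab[v], b)

    def test_flip_spec_analytic_signs(self, gene, probe_key):
        """The default flip effects give opposite per-dosage changes for the
        probe-detected sum vs the all-variant total at every dosage step."""
        spec = sq.flip_effect_spec("rs1", gene)
        detected = {v.variant_id for v in gene.variants_splicing(probe_key)}

        def sums(d):
            probe = total = 0.0
            for v in gene.variants:
                mu = spec.baseline[v.variant_id] * np.exp(
                    spec.beta[("rs1", v.variant_id)] * d
                )
                total += mu
                if v.variant_id in detected:
                    probe += mu
            return probe, total

        p0, t0 = sums(0); p1, t1 = sums(1); p2, t2 = sums(2)
        assert p0 < p1 < p2          # probe-detected abundance rises
        assert t0 > t1 > t2          # total abundance falls
        # and both junction-variant sums rise relative to the total
        for key in gene.junction_keys:
            vs = {v.variant_id for v in gene.variants_splicing(key)}
            shares = []
            for d, t in [(0, t0), (1, t1), (2, t2)]:
                j = sum(spec.baseline[v] * np.exp(spec.beta[("rs1", v)] * d) for v in vs)
                shares.append(j / t)
            assert shares[0] < shares[1] < shares[2]

    def test_disease_shift_raises_copd_mean(self, gene):
        g = sq.simulate_genotypes(400, [(1, 0.3, 0.0)], 0, seed=4)
        cov = sq.simulate_cohort(400, 200, seed=5)
        spec = sq.EffectSpec(
            baseline={"V1": 10.0, "V2": 10.0, "V3": 10.0},
            disease_shift={"V1": 0.5},
            noise_sd=0.1,
        )
        ab = sq.simulate_variant_abundances(g, cov, gene, spec, seed=6)
        copd = cov["fev1_fvc_ratio"].to_numpy() < 70
        total = ab.sum(axis=1).to_numpy()
        assert total[copd].mean() > total[~copd].mean()

    def test_missing_baseline_is_configuration_error(self, gene):
        g = sq.simulate_genotypes(10, [(1, 0.3, 0.0)], 0, seed=1)
        cov = sq.simulate_cohort(10, 0, seed=2)
        spec = sq.EffectSpec(baseline={"V1": 10.0})
        with pytest.raises(ConfigurationError):
            sq.simulate_variant_abundances(g, cov, gene, spec, seed=3)


class TestRenderReads:
    def test_coding_only_reads_have_annotated_introns(self, gene):
        ab = pd.DataFrame({"V1": [20.0], "V2": [0.0], "V3": [0.0]}, index=["s"])
        _, reads = next(sq.render_reads(ab, gene, 75, 50.0, seed=1))
        assert reads
        intron_spans = {(s, e) for s, e in gene.introns}
        seen = set()
        for r in reads:
            for j in sq.extract_junctions(r):
                assert (j.intron_start, j.intron_end) in intron_spans
                seen.add((j.intron_start, j.intron_end))
        assert seen == intron_spans  # deep coverage spans both junctions

    def test_zero_abundance_gives_no_reads(self, gene):
        ab = pd.DataFrame({"V1": [0.0], "V2": [0.0], "V3": [0.0]}, index=["s"])
        _, reads = next(sq.render_reads(ab, gene, 75, 100.0, seed=2))
        assert reads == []

    def test_invalid_read_length(self, gene):
        ab = pd.DataFrame({"V1": [1.0], "V2": [1.0], "V3": [1.0]}, index=["s"])
        with pytest.raises(InvalidParameterError):
            next(sq.render_reads(ab, gene, 0, 10.0, seed=1))

    def test_split_read_counts_match_closed_form(self, gene):
        """Aggregate split reads over 200 samples fall within 3 Poisson SDs
        of the uniform-placement expectation at depth factor 100."""
        n = 200
        rng = np.random.default_rng(11)
        ab = pd.DataFrame(
            {
                "V1": rng.uniform(3, 8, n),
                "V2": rng.uniform(4, 10, n),
                "V3": rng.uniform(2, 6, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        expected = sq.expected_junction_counts(ab, gene, 75, 100.0).sum(axis=0)
        streams = dict(sq.render_reads(ab, gene, 75, 100.0, seed=12))
        jcm = sq.count_junctions(streams, [gene])
        observed = jcm.raw_counts.sum(axis=0)
        for label in expected.index:
            lam = expected[label]
            assert abs(observed[label] - lam) < 3 * np.sqrt(lam)


class TestRenderMeasurements:
    def test_probe_signal_sums_detected_variants(self, gene, probe_key):
        # probe on exon2-exon3 junction detects V1 and V3: log2(10 + 3)
        ab = pd.DataFrame({"V1": [10.0], "V2": [5.0], "V3": [3.0]}, index=["s"])
        ms = sq.render_measurements(ab, gene, probe_key, noise_sd_probe=0.0, seed=1)
        assert ms.probe_log2.iloc[0] == pytest.approx(np.log2(13.0))

    def test_fpkm_scale_invariance(self, gene, probe_key):
        ab = pd.DataFrame({"V1": [10.0, 4.0], "V2": [5.0, 6.0], "V3": [3.0, 2.0]},
                          index=["a", "b"])
        lib = pd.Series([1e7, 2e7], index=["a", "b"])
        ms1 = sq.render_measurements(ab, gene, probe_key, 0.0, seed=1, library_sizes=lib)
        ms2 = sq.render_measurements(2 * ab, gene, probe_key, 0.0, seed=1,
                                     library_sizes=2 * lib)
        np.testing.assert_allclose(ms1.total_fpkm, ms2.total_fpkm)

    def test_unknown_probe_junction_rejected(self, gene):
        ab = pd.DataFrame({"V1": [1.0], "V2": [1.0], "V3": [1.0]}, index=["s"])
        with pytest.raises(InvalidParameterError):
            sq.render_measurements(ab, gene, ("+", 1, 2), seed=1)

    def test_count_level_sampler_matches_expectation(self, gene):
        n = 300
        ab = pd.DataFrame(
            {"V1": np.full(n, 10.0), "V2": np.full(n, 5.0), "V3": np.full(n, 3.0)},
            index=[f"s{i}" for i in range(n)],
        )
        counts, gene_reads, lib = sq.sample_junction_counts(ab, gene, 75, 100.0, seed=3)
        expected = sq.expected_junction_counts(ab, gene, 75, 100.0).sum(axis=0)
        total = counts.sum(axis=0)
        for label in expected.index:
            assert abs(total[label] - expected[label]) < 3 * np.sqrt(expected[label])
        assert (lib >= gene_reads).all()
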