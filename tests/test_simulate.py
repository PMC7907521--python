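"""Tests for the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

import migsel as ms
from migsel.simulate import DEFAULT_PREVALENCES, SYMPTOMS


class TestGenGenotypes:
    def test_degenerate_maf_rejected(self):
        with pytest.raises(ms.ValidationError):
            ms.gen_genotypes(10, [0.0])
        with pytest.raises(ms.ValidationError):
            ms.gen_genotypes(10, [0.6])
        with pytest.raises(ms.ValidationError):
            ms.gen_genotypes(0, [0.3])

    def test_hwe_proportions(self):
        geno = ms.gen_genotypes(200000, [0.3], seed=1)
        d = geno.dosages[:, 0]
        props = np.bincount(d.astype(int), minlength=3) / d.size
        assert props == pytest.approx([0.49, 0.42, 0.09], abs=0.006)
        assert d.mean() == pytest.approx(0.60, abs=0.01)

    def test_hwe_goodness_of_fit(self):
        q = 0.25
        geno = ms.gen_genotypes(10000, [q], seed=42)
        obs = np.bincount(geno.dosages[:, 0].astype(int), minlength=3)
        exp = 10000 * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        p = stats.chisquare(obs, exp).pvalue
        assert p > 0.001

    def test_hard_calls(self):
        geno = ms.gen_genotypes(500, [0.5, 0.1], seed=2)
        assert np.isin(geno.dosages, [0, 1, 2]).all()


class TestTrichotomousGenerator:
    def test_null_is_genotype_free(self):
        g = np.repeat([0.0, 1.0, 2.0], 40000)
        params = dict(alpha_minus=np.log(0.5), alpha_plus=np.log(0.5))
        y = ms.gen_phenotypes_trichotomous(g, "null", params, seed=3)
        for dose in (0, 1, 2):
            frac = np.bincount(y[g == dose], minlength=3) / 40000
            assert frac == pytest.approx([0.5, 0.25, 0.25], abs=0.01)

    def test_basic_with_zero_beta_equals_null(self):
        g = np.random.default_rng(4).binomial(2, 0.3, 5000).astype(float)
        params = dict(alpha_minus=np.log(0.5), alpha_plus=np.log(0.25))
        y0 = ms.gen_phenotypes_trichotomous(g, "null", params, seed=9)
        y1 = ms.gen_phenotypes_trichotomous(
            g, "basic", dict(params, beta_minus=0.0, beta_plus=0.0), seed=9)
        assert np.array_equal(y0, y1)

    def test_subset_slope_recovered_by_logistic_refit(self):
        """Empirical case-with-symptom log-odds slope is ~ln 2; absent ~0."""
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.3, 50000).astype(float)
        params = dict(alpha_minus=np.log(0.5), alpha_plus=np.log(0.25),
                      beta_minus=0.0, beta_plus=np.log(2))
        y = ms.gen_phenotypes_trichotomous(g, "subset", params, seed=7)
        keep2 = y != 1
        est2 = ms.adjusted_logistic(g[keep2], (y[keep2] == 2).astype(int))
        keep1 = y != 2
        est1 = ms.adjusted_logistic(g[keep1], (y[keep1] == 1).astype(int))
        assert est2.beta == pytest.approx(np.log(2), abs=0.06)
        assert est1.beta == pytest.approx(0.0, abs=0.06)

    def test_constraint_violation_rejected(self):
        g = np.zeros(4)
        with pytest.raises(ms.ValidationError):
            ms.gen_phenotypes_trichotomous(
                g, "subset", dict(alpha_minus=0, alpha_plus=0,
                                  beta_minus=0.5, beta_plus=0.5))


class TestGenCohort:
    def test_case_count_near_binomial_mean(self):
        cfg = ms.SimConfig(n_participants=21111, maf_per_snp=[0.3],
                           case_fraction=0.14, prior_fraction=0.0, seed=8)
        coh = ms.gen_cohort(cfg)
        n_active = (coh.migraine_status == "active").sum()
        se = np.sqrt(21111 * 0.14 * 0.86)
        assert abs(n_active - 2955.5) < 4 * se

    def test_symptom_prevalences_match_defaults(self):
        cfg = ms.SimConfig(n_participants=80000, maf_per_snp=[0.3],
                           case_fraction=0.5, prior_fraction=0.0, seed=9)
        coh = ms.gen_cohort(cfg)
        act = coh.migraine_status == "active"
        means = np.nanmean(coh.symptoms[act], axis=0)
        for j, s in enumerate(SYMPTOMS):
            assert means[j] == pytest.approx(DEFAULT_PREVALENCES[s], abs=0.012), s
        # aura specifically sits near 39.2%
        assert means[0] == pytest.approx(0.392, abs=0.012)

    def test_latent_class_mixture_mean(self):
        truth = ms.LcaTruth(pi=[0.6, 0.4],
                            rho=np.vstack([np.full(10, 0.9), np.full(10, 0.1)]))
        cfg = ms.SimConfig(n_participants=40000, maf_per_snp=[0.3],
                           case_fraction=0.5, prior_fraction=0.0,
                           symptom_model="latent_class", lca_truth=truth, seed=10)
        coh = ms.gen_cohort(cfg)
        act = coh.migraine_status == "active"
        means = np.nanmean(coh.symptoms[act], axis=0)
        assert means == pytest.approx(np.full(10, 0.58), abs=0.015)

    def test_latent_mode_requires_truth(self):
        with pytest.raises(ms.ValidationError):
            ms.SimConfig(symptom_model="latent_class")

    def test_symptoms_only_for_active(self):
        cfg = ms.SimConfig(n_participants=3000, maf_per_snp=[0.3], seed=11)
        coh = ms.gen_cohort(cfg)
        act = coh.migraine_status == "active"
        assert not np.isnan(coh.symptoms[act]).any()
        assert np.isnan(coh.symptoms[~act]).all()

    def test_determinism(self, tmp_path):
        from migsel.io import write_cohort
        for d in ("a", "b"):
            cfg = ms.SimConfig(n_participants=500, maf_per_snp=[0.3, 0.1], seed=12)
            write_cohort(tmp_path / d, ms.gen_cohort(cfg))
        for name in ("cohort.vcf", "cohort_genotypes.tsv",
                     "cohort_phenotypes.csv", "cohort_truth.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_injected_effect_recovered_end_to_end(self):
        eff = ms.SnpEffect(snp="snp1", model="subset", target="nausea_vomiting",
                           beta_plus=np.log(1.8))
        cfg = ms.SimConfig(n_participants=50000, maf_per_snp=[0.3],
                           case_fraction=0.3, prior_fraction=0.0,
                           snp_effects=[eff], seed=13)
        coh = ms.gen_cohort(cfg)
        act = coh.migraine_status == "active"
        ctrl = coh.migraine_status == "none"
        keep = act | ctrl
        sym = np.nan_to_num(coh.symptoms[:, SYMPTOMS.index("nausea_vomiting")]) == 1
        y = ms.trichotomize(act[keep], (sym & act)[keep], ctrl[keep])
        fit = ms.fit_model(coh.genotypes.dosages[keep, 0], y, "subset")
        assert fit.estimates["beta_plus"] == pytest.approx(np.log(1.8), abs=0.05)
        assert coh.truth["per_snp"]["snp1"] == "subset"

    def test_all_null_cohort_symptoms_independent_of_genotype(self):
        """Trend-test p-values across null SNPs are ~Uniform(0,1)."""
        cfg = ms.SimConfig(n_participants=4000, maf_per_snp=[0.3] * 120,
                           case_fraction=0.3, prior_fraction=0.0, seed=14)
        coh = ms.gen_cohort(cfg)
        act = coh.migraine_status == "active"
        aura = np.nan_to_num(coh.symptoms[:, 0]) == 1
        pvals = []
        for j in range(120):
            est = ms.adjusted_logistic(coh.genotypes.dosages[act, j],
                                       aura[act].astype(int))
            pvals.append(est.wald_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLdR2:
    def test_identity_and_flip(self):
        g = np.array([0.0, 1, 2, 0, 1])
        assert ms.ld_r2(g, g) == pytest.approx(1.0)
        assert ms.ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_value(self):
        g1 = np.array([0.0, 1, 2, 0])
        g2 = np.array([0.0, 1, 1, 1])
        r = np.corrcoef(g1, g2)[0, 1]
        assert ms.ld_r2(g1, g2) == pytest.approx(r * r, abs=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ms.ValidationError):
            ms.ld_r2(np.ones(5), np.array([0.0, 1, 2, 0, 1]))
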