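"""Generator contracts: LD structure, phenotype model, GWAS scan,
outcome model and full-chain causal-effect recovery."""
import numpy as np
import pytest
from scipy import stats

from sumstat_mr.mr import MendelianRandomization
from sumstat_mr.simulate import (SimConfig, bp_medication_adjust,
                                 cohort_gwas, prep_phenotype,
                                 simulate_genotypes, simulate_metabolite,
                                 simulate_outcome,
                                 simulate_two_sample_study)
from sumstat_mr.sumstats import harmonize_tables


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(maf_range=(0.0, 0.5)),
        dict(maf_range=(0.1, 0.6)),
        dict(h2=1.0),
        dict(tau2=-1.0),
        dict(ld_blocks=[(3, 0.5)], m_variants=4),
        dict(pleiotropy_mode="weird"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=3, m_variants=10, n_exposure_sample=500)
        d1, ld1 = simulate_genotypes(cfg)
        d2, ld2 = simulate_genotypes(cfg)
        assert np.array_equal(d1, d2)
        assert np.array_equal(ld1.R, ld2.R)

    def test_independent_blocks_have_null_ld(self):
        cfg = SimConfig(seed=4, m_variants=40, n_exposure_sample=10_000)
        _, ld = simulate_genotypes(cfg)
        off = np.abs(ld.R[~np.eye(40, dtype=bool)])
        assert np.quantile(off, 0.99) < 0.05

    @pytest.mark.parametrize("rho", [0.5, 0.9])
    def test_block_correlation_matches_bivariate_normal_oracle(self, rho):
        """Realized dosage r for a correlated block agrees with the
        thresholded-bivariate-normal orthant computation (the dosage r
        is attenuated relative to the latent rho: the phi coefficient of
        binary indicators at rho = 0.9 is ~0.71, not 0.9)."""
        maf = 0.3
        cfg = SimConfig(seed=5, m_variants=2, ld_blocks=[(2, rho)],
                        maf_range=(maf, maf), n_exposure_sample=10_000)
        _, ld = simulate_genotypes(cfg, mafs=np.array([maf, maf]))
        t = stats.norm.ppf(maf)
        p11 = stats.multivariate_normal(mean=[0, 0],
                                        cov=[[1, rho], [rho, 1]]).cdf([t, t])
        oracle = (p11 - maf**2) / (maf * (1 - maf))
        assert 0.0 < ld.R[0, 1] < rho          # attenuated, same sign
        assert abs(ld.R[0, 1] - oracle) < 0.03

    def test_eafs_match_configured_mafs(self):
        n = 10_000
        mafs = np.array([0.05, 0.2, 0.4])
        cfg = SimConfig(seed=6, m_variants=3, n_exposure_sample=n)
        _, ld = simulate_genotypes(cfg, mafs=mafs)
        tol = 4 * np.sqrt(mafs * (1 - mafs) / (2 * n))
        assert (np.abs(ld.eaf - mafs) < tol).all()


class TestMetabolite:
    def test_sex_dimorphic_standardized_effects_recovered(self):
        """Configured 3:1 female/male within-sex effects come back from
        within-sex standardized association at n = 40,000."""
        n = 40_000
        # default architecture: dominant locus 0.69 (F) vs 0.23 (M)
        cfg = SimConfig(seed=31, m_variants=24, n_exposure_sample=n)
        rng = np.random.default_rng(31)
        dos, _ = simulate_genotypes(cfg, n=n, rng=rng)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        raw = simulate_metabolite(dos, sex, cfg, rng=rng)
        betas = {}
        for label in "FM":
            mask = sex == label
            y = prep_phenotype(raw[mask])
            betas[label] = cohort_gwas(dos[mask], y).df.loc[0, "beta"]
        assert 2.6 <= betas["F"] / betas["M"] <= 3.4

    def test_null_effects_give_null_scan(self):
        """With all true effects zero nothing approaches genome-wide
        significance across 10,000 variants."""
        n, m = 1000, 10_000
        cfg = SimConfig(seed=32, m_variants=m, maf_range=(0.05, 0.5),
                        beta_f=np.zeros(m), beta_m=np.zeros(m),
                        n_exposure_sample=n)
        rng = np.random.default_rng(32)
        dos, _ = simulate_genotypes(cfg, n=n, rng=rng, with_ld=False)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        raw = simulate_metabolite(dos, sex, cfg, rng=rng)
        g = cohort_gwas(dos, prep_phenotype(raw))
        assert (g.df["p"] < 5e-8).sum() == 0
        # and the scan is calibrated at the 5% level
        frac = (g.df["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m) + 0.01

    def test_infeasible_sd_unit_effects_rejected(self):
        cfg = SimConfig(seed=33, m_variants=2, beta_f=[2.0, 2.0],
                        beta_m=[2.0, 2.0], n_exposure_sample=500)
        dos, _ = simulate_genotypes(cfg, n=500)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_metabolite(dos, np.array(["F", "M"] * 250), cfg)


class TestPrepPhenotype:
    def test_extreme_value_clipped_to_five_sds(self):
        rng = np.random.default_rng(0)
        y = rng.lognormal(0, 0.3, 5000)
        logy = np.log(y)
        mu, sd = logy.mean(), logy.std()
        y[0] = np.exp(mu + 7 * sd)
        logy = np.log(y)
        mu, sd = logy.mean(), logy.std()
        out = prep_phenotype(y)
        clipped_max = (np.clip(logy, mu - 5 * sd, mu + 5 * sd)).max()
        # position of the clipped value is preserved after z-scoring
        assert np.argmax(out) == 0
        expect = (clipped_max - np.clip(logy, mu - 5 * sd, mu + 5 * sd).mean())
        assert np.isclose(out[0] * np.clip(logy, mu - 5 * sd, mu + 5 * sd).std(),
                          expect)

    def test_no_outliers_means_winsorization_is_identity(self):
        rng = np.random.default_rng(1)
        y = rng.lognormal(0, 0.2, 2000)
        logy = np.log(y)
        direct = (logy - logy.mean()) / logy.std()
        assert np.allclose(prep_phenotype(y), direct, atol=1e-12)

    def test_output_standardized(self):
        out = prep_phenotype(np.random.default_rng(2).lognormal(1, 0.4, 1000))
        assert abs(out.mean()) < 1e-12 and abs(out.std() - 1) < 1e-12

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            prep_phenotype(np.array([1.0, 0.0, 2.0]))


class TestBPAdjust:
    def test_treated_individuals_offset(self):
        sbp, dbp = bp_medication_adjust([140.0, 120.0], [90.0, 80.0],
                                        [True, False])
        assert list(sbp) == [155.0, 120.0]
        assert list(dbp) == [100.0, 80.0]

    def test_inputs_not_mutated(self):
        sbp_in = np.array([140.0])
        bp_medication_adjust(sbp_in, np.array([90.0]), np.array([True]))
        assert sbp_in[0] == 140.0


class TestCohortGWAS:
    def test_recovers_programmed_effect_within_sampling_error(self):
        n = 10_000
        rng = np.random.default_rng(41)
        cfg = SimConfig(seed=41, m_variants=3, n_exposure_sample=n)
        dos, _ = simulate_genotypes(cfg, n=n, rng=rng)
        y = 0.5 * dos[:, 1] + rng.standard_normal(n)
        g = cohort_gwas(dos, y).df
        assert abs(g.loc[1, "beta"] - 0.5) < 3 * g.loc[1, "se"]

    def test_permuted_phenotype_is_calibrated(self):
        n, m = 2000, 400
        rng = np.random.default_rng(42)
        cfg = SimConfig(seed=42, m_variants=m, n_exposure_sample=n)
        dos, _ = simulate_genotypes(cfg, n=n, rng=rng, with_ld=False)
        y = rng.permutation(0.5 * dos[:, 0] + rng.standard_normal(n))
        frac = (cohort_gwas(dos, y).df["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m) + 0.01

    def test_noise_covariate_shrinks_se_keeps_beta(self):
        n = 5000
        rng = np.random.default_rng(43)
        cfg = SimConfig(seed=43, m_variants=2, n_exposure_sample=n)
        dos, _ = simulate_genotypes(cfg, n=n, rng=rng)
        noise = rng.standard_normal(n)
        y = 0.3 * dos[:, 0] + noise
        plain = cohort_gwas(dos, y).df
        adj = cohort_gwas(dos, y, covariates=noise[:, None]).df
        assert adj.loc[0, "se"] < plain.loc[0, "se"]
        assert abs(adj.loc[0, "beta"] - 0.3) < 3 * adj.loc[0, "se"]

    def test_monomorphic_variant_emitted_as_na(self):
        dos = np.column_stack([np.zeros(100), np.random.default_rng(0).integers(0, 3, 100)])
        g = cohort_gwas(dos, np.random.default_rng(1).normal(size=100))
        assert np.isnan(g.df.loc[0, "beta"])
        assert "monomorphic" in g.report.messages[0]

    def test_binary_outcome_uses_log_odds_scale(self):
        n = 4000
        rng = np.random.default_rng(44)
        cfg = SimConfig(seed=44, m_variants=2, n_exposure_sample=n,
                        outcome_type="binary", case_fraction=0.3, theta=0.0,
                        pleiotropy_mode="directional", tau2=0.0, mu_alpha=0.4,
                        pleiotropy_fraction=1.0)
        dos, _ = simulate_genotypes(cfg, n=n, rng=rng)
        y, alpha = simulate_outcome(cfg, dosages=dos, rng=rng)
        assert abs(y.mean() - 0.3) < 0.02
        g = cohort_gwas(dos, y, binary=True).df
        # both variants raise liability, hence positive log-odds
        assert (g["beta"] > 0).all()


class TestOutcome:
    def test_null_effect_centred_ivw(self):
        """theta = 0 with no pleiotropy: IVW estimates centre on zero
        over replicate studies."""
        ests = []
        for r in range(40):
            cfg = SimConfig(seed=70_000 + r, theta=0.0,
                            n_exposure_sample=4000, n_outcome_sample=4000)
            study = simulate_two_sample_study(cfg)
            h = harmonize_tables(study["exposure"].df, study["outcome"].df)
            ests.append(MendelianRandomization.from_harmonized(h).fit("ivw").theta)
        assert abs(np.mean(ests)) < 3 * np.std(ests) / np.sqrt(len(ests))

    def test_case_fraction_respected(self):
        cfg = SimConfig(seed=71, outcome_type="binary", case_fraction=0.1,
                        n_outcome_sample=5000)
        y, _ = simulate_outcome(cfg, exposure=np.random.default_rng(71).normal(size=5000))
        assert abs(y.mean() - 0.1) < 0.01


class TestFullChain:
    def test_causal_effect_recovery_and_ci_coverage(self):
        """Simulate -> GWAS both samples -> harmonize -> IVW recovers
        theta = 0.2; 95% CI coverage over 200 seeds stays nominal."""
        theta = 0.2
        covered, within = 0, 0
        reps = 200
        for r in range(reps):
            cfg = SimConfig(seed=80_000 + r, theta=theta,
                            n_exposure_sample=10_000, n_outcome_sample=10_000)
            study = simulate_two_sample_study(cfg)
            h = harmonize_tables(study["exposure"].df, study["outcome"].df)
            res = MendelianRandomization.from_harmonized(h).fit("ivw")
            covered += res.ci_low <= theta <= res.ci_high
            within += abs(res.theta - theta) <= 3 * res.se
        assert 0.92 <= covered / reps <= 0.98
        assert within / reps > 0.99


class TestTwoSampleDesign:
    def test_reproducible_and_emits_truth(self):
        cfg = SimConfig(seed=90, n_exposure_sample=1000,
                        n_outcome_sample=800)
        a = simulate_two_sample_study(cfg)
        b = simulate_two_sample_study(cfg)
        assert a["exposure"].df.equals(b["exposure"].df)
        assert a["outcome"].df.equals(b["outcome"].df)
        assert a["truth"]["theta"] == cfg.theta
        assert a["exposure"].n_total == 1000
        assert a["outcome"].n_total == 800
        assert "seed" in cfg.to_json()
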