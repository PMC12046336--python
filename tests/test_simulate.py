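import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dqtl import ld, simulate
from dqtl.simulate import (
    PlantedEffect,
    PlantedQTL,
    SimulationConfig,
    ancestry_frequencies,
    simulate_cohort,
    simulate_genotypes,
    simulate_loop_anchors,
    simulate_molecular_traits,
)


class TestConfigValidation:
    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=0)

    def test_bad_maf_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.5, 0.1))

    def test_bad_driver_freq(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_drivers=1, driver_freqs=[1.5])

    def test_block_lengths_must_be_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(block_lengths=[3, 0], n_snps=3)


class TestGenotypes:
    def test_seed_determinism(self, small_config):
        a = simulate_genotypes(small_config)
        b = simulate_genotypes(small_config)
        assert np.array_equal(a.dosage, b.dosage, equal_nan=True)
        pd.testing.assert_frame_equal(a.snp_table, b.snp_table)

    def test_maf_invariant_matches_dosage(self, small_cohort):
        maf = np.minimum(np.nanmean(small_cohort.dosage, axis=0) / 2,
                         1 - np.nanmean(small_cohort.dosage, axis=0) / 2)
        np.testing.assert_allclose(small_cohort.snp_table["maf"], maf, atol=1e-12)

    def test_perfect_ld_limit(self):
        cfg = SimulationConfig(n_patients=800, n_snps=12, block_lengths=[12],
                               maf_range=(0.3, 0.5),
                               ld_decay=0.0, n_ancestral_haplotypes=2, seed=1)
        c = simulate_genotypes(cfg)
        k = c.dosage.shape[1]
        assert k >= 2
        for i in range(k):
            for j in range(i + 1, k):
                est = ld.two_locus_ld(c.dosage[:, i], c.dosage[:, j])
                assert est.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_cross_block_independence(self):
        n = 2000
        cfg = SimulationConfig(n_patients=n, n_snps=10, block_lengths=[5, 5],
                               ld_decay=0.5, seed=2)
        c = simulate_genotypes(cfg)
        left = c.snp_table[c.snp_table["block"] == 0].index
        right = c.snp_table[c.snp_table["block"] == 1].index
        tol = 3 / np.sqrt(n)
        for i in left[:3]:
            for j in right[:3]:
                r = np.corrcoef(c.dosage[:, i], c.dosage[:, j])[0, 1]
                assert r ** 2 < tol

    def test_missingness_rate(self):
        cfg = SimulationConfig(n_patients=500, n_snps=40, missing_rate=0.1, seed=3)
        c = simulate_genotypes(cfg)
        frac = np.isnan(c.dosage).mean()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_no_duplicate_patients(self, small_cohort):
        assert len(set(small_cohort.samples)) == len(small_cohort.samples)


class TestDrivers:
    def test_marginal_frequency_hits_target(self):
        cfg = SimulationConfig(n_patients=10_000, n_snps=20, n_drivers=1,
                               driver_freqs=[0.20], seed=4)
        c = simulate_cohort(cfg)
        obs = c.drivers["driver00"].mean()
        assert obs == pytest.approx(0.20, abs=0.012)  # binomial SE bound

    def test_planted_or_recovered_from_genotype_table(self):
        cfg = SimulationConfig(
            n_patients=20_000, n_snps=20, n_drivers=1, driver_freqs=[0.3],
            maf_range=(0.25, 0.35), seed=5,
            planted_effects=[PlantedEffect("snp00005", "driver00", np.log(2))])
        c = simulate_cohort(cfg)
        g = c.dosage_of("snp00005")
        y = c.drivers["driver00"].to_numpy()
        # 2x3 genotype table: per-allele OR from het vs hom-ref odds
        odds0 = y[g == 0].mean() / (1 - y[g == 0].mean())
        odds1 = y[g == 1].mean() / (1 - y[g == 1].mean())
        odds2 = y[g == 2].mean() / (1 - y[g == 2].mean())
        assert odds1 / odds0 == pytest.approx(2.0, rel=0.15)
        assert odds2 / odds1 == pytest.approx(2.0, rel=0.25)

    def test_null_effect_chi2_uniform(self):
        ps = []
        for seed in range(40):
            cfg = SimulationConfig(n_patients=500, n_snps=6, n_drivers=1,
                                   driver_freqs=[0.3], seed=seed)
            c = simulate_cohort(cfg)
            g = c.dosage[:, 0]
            y = c.drivers["driver00"].to_numpy()
            tab = pd.crosstab(g, y)
            if tab.shape == (3, 2) and (tab.values >= 1).all():
                ps.append(stats.chi2_contingency(tab)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unreachable_frequency_names_driver(self):
        cfg = SimulationConfig(n_patients=100, n_snps=10, n_drivers=1,
                               driver_freqs=[0.5], seed=6)
        c = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        c.covariates = simulate.simulate_covariates(100, rng)
        effect = [PlantedEffect(c.snp_table["id"].iloc[0], "driver00", 200.0)]
        with pytest.raises(ValueError, match="driver00"):
            simulate.simulate_drivers(c, effect, cfg)

    def test_unknown_planted_snp_rejected(self):
        cfg = SimulationConfig(n_patients=50, n_snps=5, n_drivers=1,
                               driver_freqs=[0.3], seed=7)
        c = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        c.covariates = simulate.simulate_covariates(50, rng)
        with pytest.raises(ValueError, match="unknown SNP"):
            simulate.simulate_drivers(c, [PlantedEffect("nope", "driver00", 0.5)], cfg)

    def test_replication_cohort_drops_timing(self):
        cfg = SimulationConfig(n_patients=100, n_snps=10, n_drivers=4, seed=8)
        rep = simulate_cohort(cfg, timing_available=False)
        assert set(rep.driver_meta["timing"]) == {"NA"}


class TestLoopAnchors:
    def driver_regions(self, cohort):
        return {d: cohort.driver_region(d) for d in cohort.drivers.columns}

    def test_fraction_zero_no_spatial_regions(self, small_cohort):
        from dqtl import regions as reg_mod

        anchors = simulate_loop_anchors(
            small_cohort.snp_table, self.driver_regions(small_cohort),
            planted_snp_ids={"driver00": small_cohort.snp_table["id"].iloc[0]},
            fraction=0.0, n_background=5, seed=0)
        for d in small_cohort.drivers.columns:
            out = reg_mod.spatial_regions(small_cohort.driver_region(d), anchors,
                                          min_cell_lines=2)
            assert len(out) == 0

    def test_single_cell_line_loop_excluded(self, small_cohort):
        from dqtl import regions as reg_mod

        snp = small_cohort.snp_table["id"].iloc[-1]
        anchors = simulate_loop_anchors(
            small_cohort.snp_table, {"driver00": small_cohort.driver_region("driver00")},
            planted_snp_ids={"driver00": snp}, cell_lines=("LNCaP",),
            fraction=1.0, n_background=0, seed=1)
        out = reg_mod.spatial_regions(small_cohort.driver_region("driver00"), anchors,
                                      min_cell_lines=2)
        assert len(out) == 0

    def test_planted_loop_two_cell_lines_included(self, small_cohort):
        from dqtl import regions as reg_mod

        snp = small_cohort.snp_table["id"].iloc[-1]
        pos = int(small_cohort.snp_table["pos"].iloc[-1])
        anchors = simulate_loop_anchors(
            small_cohort.snp_table, {"driver00": small_cohort.driver_region("driver00")},
            planted_snp_ids={"driver00": snp}, cell_lines=("LNCaP", "DU145"),
            fraction=1.0, n_background=0, seed=2)
        out = reg_mod.spatial_regions(small_cohort.driver_region("driver00"), anchors,
                                      min_cell_lines=2)
        assert out.contains(small_cohort.snp_table["chrom"].iloc[-1], pos)


class TestMolecularTraits:
    def test_null_beta_uniform_p(self, small_cohort):
        from dqtl import downstream as ds

        ps = []
        for seed in range(40):
            tumor, ref, tt = simulate_molecular_traits(small_cohort, [], n_traits=3,
                                                       seed=seed)
            g = small_cohort.dosage[:, 0]
            y = tumor.iloc[:, 0].to_numpy()
            beta, se, p = ds._ols_test(y, g, None)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_beta_ci_coverage(self):
        cfg = SimulationConfig(n_patients=427, n_snps=10, n_drivers=1,
                               driver_freqs=[0.3], seed=9)
        cohort = simulate_cohort(cfg)
        from dqtl import downstream as ds

        snp = cohort.snp_table["id"].iloc[0]
        covered = 0
        reps = 120
        for seed in range(reps):
            tumor, _, _ = simulate_molecular_traits(
                cohort, [PlantedQTL(snp, "trait000", 0.5)], n_traits=1,
                noise_sd=1.0, seed=seed)
            g = cohort.dosage_of(snp)
            beta, se, p = ds._ols_test(tumor["trait000"].to_numpy(), g, None)
            covered += abs(beta - 0.5) <= 1.96 * se
        assert covered / reps == pytest.approx(0.95, abs=0.05)

    def test_tumor_specific_effect_flagged_downstream(self, small_cohort):
        from dqtl import downstream as ds

        snp = small_cohort.snp_table["id"].iloc[0]
        pos = int(small_cohort.snp_table["pos"].iloc[0])
        tumor, ref, tt = simulate_molecular_traits(
            small_cohort, [PlantedQTL(snp, "trait000", 1.2, tumor_specific=True)],
            n_traits=4, noise_sd=0.4, seed=3)
        cov = small_cohort.covariates[["PC1", "PC2", "PC3", "PC4", "PC5", "age"]]
        g = small_cohort.dosage_of(snp)
        rt = ds.molecular_qtl(snp, g, pos, "1", tumor, tt, cov)
        rr = ds.molecular_qtl(snp, g, pos, "1", ref, tt, cov, cohort="reference")
        flags = ds.tumor_specificity(rt, rr)
        hit = flags[flags["trait_id"] == "trait000"]
        assert bool(hit["tumor_specific"].iloc[0])


class TestAncestryPanels:
    def test_zero_fst_reproduces_maf(self, small_cohort):
        out = ancestry_frequencies(small_cohort.snp_table, {"EUR": 0.0}, seed=0)
        np.testing.assert_allclose(out["vaf"], small_cohort.snp_table["maf"], atol=1e-12)

    def test_balding_nichols_mean_and_spread(self, small_cohort):
        out = ancestry_frequencies(small_cohort.snp_table, {"AFR": 0.1}, seed=1)
        # per-SNP draws spread around the base frequency
        merged = out.merge(small_cohort.snp_table[["id", "maf"]],
                           left_on="snp", right_on="id")
        resid = merged["vaf"] - merged["maf"]
        assert abs(resid.mean()) < 0.05
        assert resid.std() > 0.01
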