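import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dqtl import downstream as ds
from dqtl.downstream import AncestryVAFRecord


class TestRankInverseNormal:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=200)
        a = ds.rank_inverse_normal(x)
        b = ds.rank_inverse_normal(np.log(x))  # monotone transform
        np.testing.assert_allclose(a, b)

    def test_result_is_gaussian_like(self):
        rng = np.random.default_rng(1)
        z = ds.rank_inverse_normal(rng.exponential(size=5000))
        assert abs(np.mean(z)) < 0.01
        assert abs(np.std(z) - 1) < 0.02


class TestMolecularQTL:
    def setup_traits(self, n=427, beta=0.0, seed=0, n_traits=5):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, n).astype(float)
        cov = pd.DataFrame({f"PC{i}": rng.normal(size=n) for i in range(1, 6)}
                           | {"age": rng.normal(65, 7, n)})
        traits = {}
        for t in range(n_traits):
            traits[f"t{t}"] = rng.normal(size=n) + (beta * g if t == 0 else 0)
        tm = pd.DataFrame(traits)
        tt = pd.DataFrame({"trait_id": list(traits), "chrom": "1",
                           "pos": [1000 * (t + 1) for t in range(n_traits)]})
        return g, tm, tt, cov

    def test_planted_beta_detected(self):
        hits = 0
        for seed in range(30):
            g, tm, tt, cov = self.setup_traits(beta=0.4, seed=seed)
            res = ds.molecular_qtl("rs1", g, 2000, "1", tm, tt, cov, window=500_000)
            row = res[res["trait_id"] == "t0"]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 24  # >= 80% power

    def test_window_restricts_traits(self):
        g, tm, tt, cov = self.setup_traits()
        res = ds.molecular_qtl("rs1", g, 1000, "1", tm, tt, cov, window=1500)
        assert set(res["trait_id"]) == {"t0", "t1"}
        empty = ds.molecular_qtl("rs1", g, 10**9, "1", tm, tt, cov, window=100)
        assert len(empty) == 0

    def test_permuted_genotypes_uniform_p(self):
        rng = np.random.default_rng(3)
        ps = []
        for seed in range(60):
            g, tm, tt, cov = self.setup_traits(beta=0.8, seed=seed)
            res = ds.molecular_qtl("rs1", rng.permutation(g), 2000, "1", tm, tt, cov)
            ps.extend(res["p"].tolist())
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rint_transform_rank_invariance(self):
        g, tm, tt, cov = self.setup_traits(beta=0.5, seed=4)
        res1 = ds.molecular_qtl("rs1", g, 1000, "1", tm, tt, cov, transform="rint")
        tm2 = tm.copy()
        tm2["t0"] = np.exp(tm2["t0"])  # monotone transform of the trait
        res2 = ds.molecular_qtl("rs1", g, 1000, "1", tm2, tt, cov, transform="rint")
        r1 = res1[res1["trait_id"] == "t0"].iloc[0]
        r2 = res2[res2["trait_id"] == "t0"].iloc[0]
        assert r1["p"] == pytest.approx(r2["p"], rel=1e-10)


class TestTumorSpecificity:
    def frame(self, q, beta):
        return pd.DataFrame({"snp": ["rs1"], "trait_id": ["t0"],
                             "beta": [beta], "se": [0.1], "p": [q], "q": [q],
                             "cohort": ["x"]})

    @pytest.mark.parametrize("qt,qr,bt,br,expected", [
        (0.05, 0.5, 1.0, 1.0, True),    # tumor sig, ref not
        (0.05, 0.05, 1.0, 1.0, False),  # both sig, same sign
        (0.05, 0.05, 1.0, -1.0, True),  # both sig, opposite sign
        (0.5, 0.5, 1.0, 1.0, False),
        (0.5, 0.05, 1.0, 1.0, False),
        (0.05, 0.5, -1.0, -1.0, True),
        (0.5, 0.05, 1.0, -1.0, False),
        (0.05, 0.11, 1.0, 1.0, True),   # boundary: q_r just above 0.10
    ])
    def test_truth_table(self, qt, qr, bt, br, expected):
        out = ds.tumor_specificity(self.frame(qt, bt), self.frame(qr, br))
        assert bool(out["tumor_specific"].iloc[0]) == expected

    def test_unmatched_pair_is_na(self):
        t = self.frame(0.05, 1.0)
        r = self.frame(0.05, 1.0).assign(trait_id="other")
        out = ds.tumor_specificity(t, r)
        assert out["tumor_specific"].iloc[0] is None


def fisher_exact_oracle(table):
    """Exact two-sided Fisher by table enumeration (margins fixed)."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, row1)
    probs = {}
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        probs[x] = Fraction(math.comb(col1, x) * math.comb(n - col1, row1 - x), denom)
    cutoff = probs[a] * Fraction(1 + 10**-7)
    return float(sum(p for p in probs.values() if p <= cutoff))


class TestVAFAncestry:
    def test_printed_vaf_pair_significant(self):
        rec = AncestryVAFRecord("rs11203152", 0.10, 0.066, 7718, 4359)
        out = ds.vaf_ancestry_test([rec])
        assert out["fisher_p"].iloc[0] < 0.01

    def test_equal_vafs_null(self):
        rec = AncestryVAFRecord("x", 0.3, 0.3, 1000, 1000)
        out = ds.vaf_ancestry_test([rec])
        assert out["fisher_p"].iloc[0] == pytest.approx(1.0)
        assert out["allele_or"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_matches_enumeration_oracle(self):
        table = np.array([[8, 2], [1, 5]])
        p = stats.fisher_exact(table)[1]
        assert p == pytest.approx(fisher_exact_oracle(table), rel=1e-9)
        # via the record path: vaf = 8/10 over n=5 individuals etc.
        rec = AncestryVAFRecord("y", 0.8, 1 / 6, 5, 3)
        out = ds.vaf_ancestry_test([rec])
        assert out["fisher_p"].iloc[0] == pytest.approx(fisher_exact_oracle(
            rec.allele_table()), rel=1e-9)

    def test_all_margins_le_40_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            t = rng.integers(0, 20, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert stats.fisher_exact(t)[1] == pytest.approx(
                fisher_exact_oracle(t), rel=1e-8)

    def test_zero_margin_flagged(self):
        rec = AncestryVAFRecord("z", 0.0, 0.0, 100, 100)
        out = ds.vaf_ancestry_test([rec])
        assert out["fisher_p"].iloc[0] == 1.0
        assert not out["or_defined"].iloc[0]

    def test_allele_counts_reconstruction(self):
        rec = AncestryVAFRecord("rs848048", 0.49, 0.23, 7718, 4359)
        tab = rec.allele_table()
        assert tab[0].tolist() == [round(0.49 * 2 * 7718), 2 * 7718 - round(0.49 * 2 * 7718)]
        assert tab[1].tolist() == [round(0.23 * 2 * 4359), 2 * 4359 - round(0.23 * 2 * 4359)]


class TestExplainedFraction:
    def test_null_dqtl_gives_zero(self):
        out = ds.explained_fraction(5.0, 1.0, 0.3, 0.1)
        assert out.fraction == 0.0

    def test_equal_vafs_give_zero(self):
        out = ds.explained_fraction(5.0, 2.0, 0.3, 0.3)
        assert out.fraction == 0.0

    def test_variant_recorded_and_finite(self):
        for variant in ("delta2", "delta", "odds"):
            out = ds.explained_fraction(5.0, 2.0, 0.10, 0.066, variant=variant)
            assert out.formula_variant == variant
            assert np.isfinite(out.fraction)
        d2 = ds.explained_fraction(5.0, 2.0, 0.10, 0.066, "delta2").fraction
        d1 = ds.explained_fraction(5.0, 2.0, 0.10, 0.066, "delta").fraction
        assert d2 == pytest.approx(2 * d1)

    def test_or_ancestry_one_undefined(self):
        with pytest.raises(ValueError):
            ds.explained_fraction(1.0, 2.0, 0.3, 0.1)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ds.explained_fraction(5.0, 2.0, 0.3, 0.1, variant="bogus")


def chi2_scan_factory(G):
    """Cheap vectorized allelic score scan: p-value per SNP column vs labels."""
    def scan(labels):
        y = np.asarray(labels, float)
        yc = y - y.mean()
        gc = G - G.mean(axis=0)
        num = (gc * yc[:, None]).sum(axis=0) ** 2
        den = (gc ** 2).sum(axis=0) * (yc ** 2).sum(axis=0) / len(y)
        z2 = num / den
        return stats.chi2.sf(z2, df=1)
    return scan


class TestSkewTest:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.3, size=(300, 20)).astype(float)
        labels = rng.binomial(1, 0.3, 300)
        scan = chi2_scan_factory(G)
        a = ds.pvalue_skew_test(scan, labels, n_perm=100, seed=5)
        b = ds.pvalue_skew_test(scan, labels, n_perm=100, seed=5)
        assert a[0] == b[0] and np.array_equal(a[2], b[2])

    def test_frequency_preserved_in_permutations(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.3, size=(200, 10)).astype(float)
        labels = rng.binomial(1, 0.25, 200)
        seen = []

        def recording_scan(lab):
            seen.append(int(np.sum(lab)))
            return chi2_scan_factory(G)(lab)

        ds.pvalue_skew_test(recording_scan, labels, n_perm=20, seed=2)
        assert set(seen) == {int(labels.sum())}

    def test_strong_effect_extreme_p(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.3, size=(500, 20)).astype(float)
        eta = -1 + 2.0 * G[:, 0]  # one strong planted SNP dominates the skew
        labels = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        scan = chi2_scan_factory(G)
        p, obs, null = ds.pvalue_skew_test(scan, labels, n_perm=200, seed=3, add_one=True)
        assert p <= 2 / 201

    def test_too_few_pvalues_errors(self):
        with pytest.raises(ValueError, match="skew"):
            ds.pvalue_skew_test(lambda lab: [0.5, 0.5], np.array([0, 1, 1]), n_perm=5)


class TestPi0:
    def test_uniform_pvalues(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=10_000)
        assert ds.pi0_estimate(p) == pytest.approx(1.0, abs=0.05)

    def test_all_signal(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 0.01, 1000)
        assert ds.pi0_estimate(p) < 0.05

    def test_mixture(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(size=7000), rng.beta(0.05, 10, 3000)])
        assert ds.pi0_estimate(p) == pytest.approx(0.7, abs=0.05)

    def test_small_m_fallback(self):
        with pytest.warns(UserWarning, match="lambda"):
            out = ds.pi0_estimate([0.5] * 10)
        assert 0 <= out <= 1

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            ds.pi0_estimate([0.5, 1.5])


class TestEnrichmentPermutation:
    def pipeline_factory(self, qtl_snps):
        def pipeline(snp_ids):
            hits = [s for s in snp_ids if s in qtl_snps]
            return len(hits), 3 * len(hits)
        return pipeline

    def test_planted_tags_extreme(self):
        pool = [f"s{i}" for i in range(100)]
        tags = pool[:5]
        pipeline = self.pipeline_factory(set(tags))
        p_snps, p_qtls, null = ds.qtl_enrichment_permutation(
            tags, pool, pipeline, n_iter=200, seed=0, add_one=True)
        assert p_snps == pytest.approx(1 / 201)
        assert p_qtls == pytest.approx(1 / 201)

    def test_strict_estimator_zero_at_extreme(self):
        pool = [f"s{i}" for i in range(50)]
        tags = pool[:4]
        pipeline = self.pipeline_factory(set(tags))
        p_snps, _, _ = ds.qtl_enrichment_permutation(tags, pool, pipeline,
                                                     n_iter=100, seed=1)
        assert p_snps == 0.0

    def test_seed_reproducible(self):
        pool = [f"s{i}" for i in range(50)]
        pipeline = self.pipeline_factory({"s10", "s20"})
        a = ds.qtl_enrichment_permutation(pool[:5], pool, pipeline, n_iter=50, seed=9)
        b = ds.qtl_enrichment_permutation(pool[:5], pool, pipeline, n_iter=50, seed=9)
        assert a[0] == b[0] and a[1] == b[1]

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            ds.qtl_enrichment_permutation(["a", "b"], ["a"], lambda s: (0, 0))


class TestClinicalAssociation:
    def simulate(self, coding, n=2000, seed=0, kind="linear"):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, n).astype(float)
        x = {"additive": g, "dominant": (g > 0).astype(float),
             "recessive": (g == 2).astype(float)}[coding]
        if kind == "linear":
            y = 1.0 * x + rng.normal(size=n)
        else:
            y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 1.5 * x)))).astype(float)
        return g, y

    def test_additive_generative_prefers_codominant(self):
        wins = 0
        for seed in range(15):
            g, y = self.simulate("additive", seed=seed)
            out = ds.clinical_association(g, y, "linear")
            wins += out["best"] == "codominant"
        assert wins >= 10

    def test_dominant_generative_prefers_dominant(self):
        wins = 0
        for seed in range(15):
            g, y = self.simulate("dominant", seed=seed, n=4000)
            out = ds.clinical_association(g, y, "linear")
            wins += out["best"] == "dominant"
        assert wins >= 10

    def test_recessive_skipped_without_homozygotes(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(1, 0.3, 500).astype(float)  # never 2
        y = rng.normal(size=500)
        out = ds.clinical_association(g, y, "linear")
        assert "recessive" in out["skipped"]

    def test_null_phenotype_uniform_p(self):
        rng = np.random.default_rng(4)
        ps = []
        for seed in range(50):
            g = rng.binomial(2, 0.3, 300).astype(float)
            y = rng.normal(size=300)
            out = ds.clinical_association(g, y, "linear")
            ps.append(out["models"]["codominant"]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_ordinal_kind(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, 600).astype(float)
        latent = 0.8 * g + rng.logistic(size=600)
        y = np.digitize(latent, [-1, 0.5, 2, 3.5]) + 1.0
        out = ds.clinical_association(g, y, "ordinal")
        assert out["models"][out["best"]]["p"] < 0.01

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            ds.clinical_association(np.zeros(10), np.zeros(10), "cox")


class TestLatentFactors:
    def test_capture_planted_structure(self):
        rng = np.random.default_rng(0)
        n, m = 200, 30
        factor = rng.normal(size=n)
        cov = pd.DataFrame({"age": rng.normal(65, 7, n)})
        traits = pd.DataFrame(
            {f"t{j}": 0.9 * factor * rng.normal(1, 0.1) + rng.normal(size=n) * 0.5
             for j in range(m)})
        lf = ds.latent_factors(traits, cov, n_factors=3)
        r = np.corrcoef(lf["LF1"], factor)[0, 1]
        assert abs(r) > 0.9
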