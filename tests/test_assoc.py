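"""Tests of SNP QC and the additive linear-model association engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrgwas import assoc
from nmrgwas.synth import GenotypeSet, SnpSpec, simulate_genotypes


def _genotype_set(dosage: np.ndarray, mafs=None) -> GenotypeSet:
    n, m = dosage.shape
    if mafs is None:
        mafs = [float(np.nanmean(dosage[:, j]) / 2) for j in range(m)]
    snps = pd.DataFrame({
        "id": [f"s{j}" for j in range(m)],
        "chrom": ["1"] * m,
        "pos": list(range(1, m + 1)),
        "allele_a": ["A"] * m,
        "allele_b": ["G"] * m,
        "maf": mafs,
        "call_rate": [float(np.isfinite(dosage[:, j]).mean()) for j in range(m)],
    })
    return GenotypeSet(subjects=[f"S{i}" for i in range(n)], snps=snps,
                       dosage=dosage)


def ols_oracle(y, X):
    """Brute-force pseudoinverse OLS with t-CDF P for the second column."""
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[1], se, t, p


class TestSnpQC:
    def test_exact_hwe_proportions_pass(self):
        d = np.repeat([0.0, 1.0, 2.0], [49, 42, 9])[:, None]
        report, kept = assoc.snp_qc(_genotype_set(d))
        assert report["hwe_p"].iloc[0] > 0.9
        assert report["passed"].iloc[0]
        assert kept.n_snps == 1

    def test_heterozygote_deficit_fails_hwe(self):
        # counts (50, 0, 50): hand chi-square equals n = 100 exactly
        d = np.repeat([0.0, 2.0], [50, 50])[:, None]
        assert assoc.hwe_chisq_p(50, 0, 50) == pytest.approx(
            float(stats.chi2.sf(100, 1)))
        report, kept = assoc.snp_qc(_genotype_set(d))
        assert report["hwe_p"].iloc[0] < 1e-6
        assert not report["passed"].iloc[0]
        assert "hwe" in report["fail_reason"].iloc[0]
        assert kept.n_snps == 0

    def test_call_rate_threshold_edge(self):
        d = np.repeat([0.0, 1.0], [60, 40])[:, None].copy()
        d[:6, 0] = np.nan  # call rate 0.94
        report, _ = assoc.snp_qc(_genotype_set(d), call_rate_min=0.95)
        assert report["call_rate"].iloc[0] == pytest.approx(0.94)
        assert "call_rate" in report["fail_reason"].iloc[0]

    def test_monomorphic_snp_removed_on_maf(self):
        d = np.zeros((100, 1))
        report, kept = assoc.snp_qc(_genotype_set(d))
        assert report["maf"].iloc[0] == 0.0
        assert "maf" in report["fail_reason"].iloc[0]
        assert kept.n_snps == 0


class TestFitAdditiveModel:
    def test_perfect_fit_clamps_p(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, 50).astype(float)
        age = rng.uniform(25, 74, 50)
        sex = rng.integers(0, 2, 50).astype(float)
        res = assoc.fit_additive_model(d.copy(), d, age, sex)
        assert res.beta == pytest.approx(1.0, abs=1e-8)
        assert res.p <= 1e-200  # underflow territory, clamped above zero
        assert res.p >= assoc.P_FLOOR

    def test_worked_fixture_matches_algebraic_oracle(self):
        """Fixed 8-subject fixture against the normal-equations + t-CDF oracle."""
        trait = np.array([1.2, 0.7, 1.9, 1.1, 0.4, 1.6, 0.9, 1.3])
        dosage = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        age = np.array([30.0, 45, 52, 61, 28, 39, 55, 47])
        sex = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        res = assoc.fit_additive_model(trait, dosage, age, sex)
        X = np.column_stack([np.ones(8), dosage, age, sex])
        b, se, t, p = ols_oracle(trait, X)
        assert res.beta == pytest.approx(b, rel=1e-10)
        assert res.se == pytest.approx(se, rel=1e-10)
        assert res.stat == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_constant_trait_not_testable(self):
        res = assoc.fit_additive_model(
            np.ones(30), np.tile([0.0, 1, 2], 10),
            np.linspace(25, 74, 30), np.tile([0.0, 1], 15))
        assert not res.testable

    def test_too_few_complete_cases_not_testable(self):
        res = assoc.fit_additive_model(
            np.array([1.0, 2, 3, 4]), np.array([0.0, 1, 2, 0]),
            np.array([30.0, 40, 50, 60]), np.array([0.0, 1, 0, 1]))
        assert not res.testable

    def test_agreement_with_pinv_oracle_on_random_problems(self):
        """100 random small problems; relative error < 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            d = rng.integers(0, 3, n).astype(float)
            age = rng.uniform(25, 74, n)
            sex = rng.integers(0, 2, n).astype(float)
            y = 0.1 * d + 0.01 * age + rng.standard_normal(n)
            res = assoc.fit_additive_model(y, d, age, sex)
            b, se, t, p = ols_oracle(y, np.column_stack([np.ones(n), d, age, sex]))
            assert res.beta == pytest.approx(b, rel=1e-8)
            assert res.se == pytest.approx(se, rel=1e-8)
            assert res.p == pytest.approx(p, rel=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        n = 200
        d = rng.integers(0, 3, n).astype(float)
        age = rng.uniform(25, 74, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.2 * d + rng.standard_normal(n)
        base = assoc.fit_additive_model(y, d, age, sex)
        scaled = assoc.fit_additive_model(1000.0 * y, d, age, sex)
        assert scaled.beta == pytest.approx(1000 * base.beta, rel=1e-10)
        assert scaled.se == pytest.approx(1000 * base.se, rel=1e-10)
        assert scaled.stat == pytest.approx(base.stat, rel=1e-10)
        assert scaled.p == pytest.approx(base.p, rel=1e-10)

    def test_allele_flip_antisymmetry(self):
        rng = np.random.default_rng(8)
        n = 150
        d = rng.integers(0, 3, n).astype(float)
        age = rng.uniform(25, 74, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.3 * d + rng.standard_normal(n)
        a = assoc.fit_additive_model(y, d, age, sex)
        b = assoc.fit_additive_model(y, 2.0 - d, age, sex)
        assert b.beta == pytest.approx(-a.beta, rel=1e-12)
        assert b.p == pytest.approx(a.p, rel=1e-12)

    def test_statsmodels_cross_check(self):
        """Independent reference fit on one random problem."""
        import statsmodels.api as sm
        rng = np.random.default_rng(9)
        n = 120
        d = rng.integers(0, 3, n).astype(float)
        age = rng.uniform(25, 74, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.15 * d - 0.01 * age + rng.standard_normal(n)
        res = assoc.fit_additive_model(y, d, age, sex)
        X = sm.add_constant(np.column_stack([d, age, sex]))
        ref = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-10)
        assert res.p == pytest.approx(ref.pvalues[1], rel=1e-10)


class TestScan:
    def _cov(self, n, rng):
        return pd.DataFrame({"subject": [f"S{i}" for i in range(n)],
                             "age": rng.uniform(25, 74, n),
                             "sex": rng.integers(0, 2, n).astype(float)})

    def test_single_pair_equals_standalone_fit(self):
        rng = np.random.default_rng(10)
        n = 100
        gs = simulate_genotypes(n, [SnpSpec("s0", "1", 1, 0.3)], seed=1)
        cov = self._cov(n, rng)
        y = rng.standard_normal(n)
        df = assoc.scan(y[:, None], ["t0"], gs, cov)
        single = assoc.fit_additive_model(
            y, gs.dosage[:, 0], cov["age"].to_numpy(), cov["sex"].to_numpy())
        assert len(df) == 1
        assert df["BETA"].iloc[0] == pytest.approx(single.beta, rel=1e-10)
        assert df["P"].iloc[0] == pytest.approx(single.p, rel=1e-10)

    def test_exhaustive_cross_check_with_missing_values(self):
        """10 SNPs x 10 traits: each row agrees with the standalone fit on
        the same complete-case subset."""
        rng = np.random.default_rng(11)
        n = 120
        specs = [SnpSpec(f"s{j}", "1", j + 1, 0.2 + 0.02 * j) for j in range(10)]
        gs = simulate_genotypes(n, specs, seed=2, missing_rate=0.05)
        cov = self._cov(n, rng)
        Y = rng.standard_normal((n, 10))
        Y[rng.random((n, 10)) < 0.07] = np.nan
        df = assoc.scan(Y, [f"t{k}" for k in range(10)], gs, cov)
        assert len(df) == 100
        for _, row in df.iterrows():
            k = int(row["TRAIT"][1:])
            j = list(gs.snps["id"]).index(row["SNP"])
            single = assoc.fit_additive_model(
                Y[:, k], gs.dosage[:, j],
                cov["age"].to_numpy(), cov["sex"].to_numpy())
            assert row["N"] == single.n
            if single.testable:
                assert row["BETA"] == pytest.approx(single.beta, rel=1e-9)
                assert row["SE"] == pytest.approx(single.se, rel=1e-9)
                assert row["P"] == pytest.approx(single.p, rel=1e-9)
            else:
                assert not row["TESTABLE"]

    def test_all_missing_trait_flagged_not_testable(self):
        rng = np.random.default_rng(12)
        n = 60
        gs = simulate_genotypes(n, [SnpSpec("s0", "1", 1, 0.4)], seed=3)
        Y = np.column_stack([np.full(n, np.nan), rng.standard_normal(n)])
        df = assoc.scan(Y, ["dead", "alive"], gs, self._cov(n, rng))
        assert not df.loc[df["TRAIT"] == "dead", "TESTABLE"].any()
        assert df.loc[df["TRAIT"] == "alive", "TESTABLE"].all()

    def test_deterministic_trait_major_order(self):
        rng = np.random.default_rng(13)
        n = 50
        specs = [SnpSpec("b", "2", 5, 0.3), SnpSpec("a", "1", 9, 0.3)]
        gs = simulate_genotypes(n, specs, seed=4)
        Y = rng.standard_normal((n, 2))
        df = assoc.scan(Y, ["t0", "t1"], gs, self._cov(n, rng))
        assert list(df["TRAIT"]) == ["t0", "t0", "t1", "t1"]
        assert list(df["SNP"]) == ["a", "b", "a", "b"]  # by (chrom, pos)


class TestSpearman:
    def test_perfect_monotone(self):
        # identical rank structure (ties matched) gives rho exactly 1
        d = np.array([0.0, 0, 1, 1, 2, 2])
        rho, p = assoc.spearman_assoc_test(np.array([1.0, 1, 2.2, 2.2, 3.5, 3.5]), d)
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        d = np.array([0.0, 1, 2, 0, 1, 2])
        rho, _ = assoc.spearman_assoc_test(-d, d)
        assert rho == pytest.approx(-1.0)

    def test_constant_not_testable(self):
        rho, p = assoc.spearman_assoc_test(np.ones(10), np.arange(10.0))
        assert np.isnan(rho)

    def test_type_i_error_calibrated(self):
        """Null rejections at alpha=0.05 within 0.05 +- 0.02 (1,000 reps)."""
        rng = np.random.default_rng(14)
        n, reps = 200, 1000
        hits = 0
        for _ in range(reps):
            d = rng.integers(0, 3, n).astype(float)
            y = rng.standard_normal(n)
            _, p = assoc.spearman_assoc_test(y, d)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) <= 0.02

    def test_rank_order_agrees_with_linear_model_on_monotone_signal(self):
        rng = np.random.default_rng(15)
        n = 300
        age = rng.uniform(25, 74, n)
        sex = rng.integers(0, 2, n).astype(float)
        ps_lin, ps_rho = [], []
        for effect in (0.0, 0.1, 0.3):
            d = rng.integers(0, 3, n).astype(float)
            y = effect * d + rng.standard_normal(n)
            ps_lin.append(assoc.fit_additive_model(y, d, age, sex).p)
            ps_rho.append(assoc.spearman_assoc_test(y, d)[1])
        assert np.argsort(ps_lin).tolist() == np.argsort(ps_rho).tolist()
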