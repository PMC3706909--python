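"""Tests of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from nmrgwas import assoc
from nmrgwas.synth import (
    EffectSpec,
    MetaboliteSpec,
    MsReadoutSpec,
    NoiseSpec,
    PeakSpec,
    SimulationConfig,
    SnpSpec,
    simulate_cohort,
    simulate_concentrations,
    simulate_genotypes,
    simulate_ms_readouts,
    render_spectra,
)


def _cfg(**kw) -> SimulationConfig:
    base = dict(
        n_subjects=200,
        snp_specs=[SnpSpec("s1", "1", 1000, 0.3)],
        metabolite_specs=[MetaboliteSpec("m1", 0.3, 0.05)],
        peak_map=[PeakSpec("m1", center=3.599, half_width=0.002, amplitude=10.0)],
        noise=NoiseSpec(0.0, 0.0, 0.0),
        seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenotypes:
    def test_hwe_frequencies_at_half(self):
        gs = simulate_genotypes(10_000, [SnpSpec("a", "1", 1, 0.5)], seed=0)
        counts = np.bincount(gs.dosage[:, 0].astype(int), minlength=3) / 10_000
        # binomial sampling error on 10,000 draws is ~0.005 per class
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.02)

    def test_empty_cohort_is_valid(self):
        gs = simulate_genotypes(0, [SnpSpec("a", "1", 1, 0.2)], seed=0)
        assert gs.dosage.shape == (0, 1)
        assert gs.subjects == []

    def test_observed_maf_within_binomial_bounds(self):
        n, maf = 20_000, 0.3
        gs = simulate_genotypes(n, [SnpSpec("a", "1", 1, maf)], seed=123)
        observed = gs.dosage[:, 0].mean() / 2.0
        # exact-proportion oracle: allele draws are Bernoulli(maf) over 2n trials
        sd = np.sqrt(maf * (1 - maf) / (2 * n))
        assert abs(observed - maf) < 3 * sd

    @pytest.mark.parametrize("bad", [0.0, 0.6, -0.1, 1.0])
    def test_invalid_maf_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_genotypes(10, [SnpSpec("a", "1", 1, bad)], seed=0)

    def test_minor_allele_orientation(self):
        # MAF 0.5 spec can realize >0.5 observed; dosage must count the minor
        gs = simulate_genotypes(501, [SnpSpec("a", "1", 1, 0.5)], seed=5)
        assert gs.snps["maf"].iloc[0] <= 0.5
        assert gs.dosage[:, 0].mean() / 2.0 == pytest.approx(gs.snps["maf"].iloc[0])

    def test_hwe_holds_across_many_snps(self):
        """>=99% of 1,000 simulated SNPs pass HWE at P > 1e-6 (n=1,757)."""
        rng = np.random.default_rng(0)
        specs = [SnpSpec(f"s{i}", "1", i + 1, maf=float(rng.uniform(0.05, 0.5)))
                 for i in range(1000)]
        gs = simulate_genotypes(1757, specs, seed=42)
        report, _ = assoc.snp_qc(gs, call_rate_min=0.0, maf_min=0.0, hwe_p_min=1e-6)
        assert (report["hwe_p"] > 1e-6).mean() >= 0.99


class TestSimulateConcentrations:
    def test_null_effect_gives_null_slope(self):
        cfg = _cfg(n_subjects=5000, effect_specs=[],
                   metabolite_specs=[MetaboliteSpec("m1", 0.3, 0.10)])
        gs = simulate_genotypes(5000, cfg.snp_specs, seed=1)
        conc, cov, _ = simulate_concentrations(gs, cfg, seed=2)
        y = np.log10(conc.column("m1"))
        d = gs.dosage[:, 0]
        # normal-equations oracle for the simple regression slope
        X = np.column_stack([np.ones_like(d), d])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (len(y) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1]) < 2 * se

    def test_planted_effect_recovered_by_ols_oracle(self):
        cfg = _cfg(n_subjects=5000,
                   metabolite_specs=[MetaboliteSpec("m1", 0.3, 0.10)],
                   effect_specs=[EffectSpec("s1", "m1", 0.05)])
        gs = simulate_genotypes(5000, cfg.snp_specs, seed=3)
        conc, cov, truth = simulate_concentrations(gs, cfg, seed=4)
        y = np.log10(conc.column("m1"))
        d = gs.dosage[:, 0]
        X = np.column_stack([np.ones_like(d), d])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        se = np.sqrt((res[0] / (len(y) - 2)) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1] - 0.05) < 2 * se
        assert truth.effects.iloc[0]["beta"] == 0.05

    def test_noiseless_limit_is_deterministic_in_dosage(self):
        cfg = _cfg(metabolite_specs=[MetaboliteSpec("m1", 0.3, 0.0)],
                   effect_specs=[EffectSpec("s1", "m1", 0.2)])
        gs = simulate_genotypes(200, cfg.snp_specs, seed=5)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=6)
        expected = 10.0 ** (0.3 + 0.2 * gs.dosage[:, 0])
        assert np.allclose(conc.column("m1"), expected, rtol=1e-12)

    def test_effect_referencing_unknown_snp_rejected(self):
        with pytest.raises(ValueError, match="unknown SNP"):
            _cfg(effect_specs=[EffectSpec("nope", "m1", 0.1)]).validate()


class TestRenderSpectra:
    def test_empty_mixture_renders_zero(self):
        cfg = _cfg()
        gs = simulate_genotypes(5, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        conc.values[:] = np.nan  # no visible concentration
        spectra, _ = render_spectra(conc, cfg, seed=0)
        assert np.all(spectra == 0)

    def test_single_peak_argmax_at_nearest_grid_point(self):
        cfg = _cfg(n_subjects=1)
        gs = simulate_genotypes(1, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        spectra, grid = render_spectra(conc, cfg, seed=0)
        assert grid[np.argmax(spectra[0])] == pytest.approx(3.599, abs=5e-4)

    def test_rendering_linear_in_concentration(self):
        """Doubling a concentration doubles its peak area (integration oracle)."""
        cfg = _cfg(n_subjects=3)
        gs = simulate_genotypes(3, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        s1, grid = render_spectra(conc, cfg, seed=0)
        doubled = conc
        doubled.values = conc.values * 2.0
        s2, _ = render_spectra(doubled, cfg, seed=0)
        step = grid[1] - grid[0]
        area1 = s1.sum(axis=1) * step  # rectangle-rule integral
        area2 = s2.sum(axis=1) * step
        assert np.allclose(area2, 2 * area1, rtol=1e-10)
        assert np.allclose(s2, 2 * s1, rtol=1e-10, atol=1e-300)

    def test_metabolite_without_peak_warns_and_is_invisible(self):
        cfg = _cfg(metabolite_specs=[MetaboliteSpec("m1", 0.3, 0.05),
                                     MetaboliteSpec("ghost", 0.3, 0.05)])
        gs = simulate_genotypes(2, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        with pytest.warns(UserWarning, match="ghost"):
            render_spectra(conc, cfg, seed=0)

    def test_water_artifact_dominates_masked_region(self):
        cfg = _cfg(n_subjects=1)
        cfg.water = type(cfg.water)(center=4.8, half_width=0.12, amplitude=500.0)
        gs = simulate_genotypes(1, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        spectra, grid = render_spectra(conc, cfg, seed=0)
        inside = (grid > 4.6) & (grid < 5.0)
        assert spectra[0, inside].max() > 100


class TestMsReadouts:
    def test_noiseless_readout_equals_truth(self):
        cfg = _cfg(ms_readout=[MsReadoutSpec("m1", cv=0.0, missing_rate=0.0)])
        gs = simulate_genotypes(50, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        ro = simulate_ms_readouts(conc, cfg, seed=0)
        assert np.allclose(ro.column("m1"), conc.column("m1"))

    def test_high_missingness_fails_min_n_filter(self):
        n = 1757
        cfg = _cfg(n_subjects=n,
                   ms_readout=[MsReadoutSpec("m1", cv=0.0, missing_rate=0.9)])
        gs = simulate_genotypes(n, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        ro = simulate_ms_readouts(conc, cfg, seed=1)
        nonmissing = int(np.isfinite(ro.column("m1")).sum())
        # binomial expectation ~176, far below the >=300 inclusion filter
        assert nonmissing < 300
        from nmrgwas.correlate import clean_metabolite
        assert clean_metabolite(ro.column("m1"), min_n=300).excluded

    def test_empirical_cv_matches_spec(self):
        n = 10_000
        cfg = _cfg(n_subjects=n,
                   ms_readout=[MsReadoutSpec("m1", cv=0.1, missing_rate=0.0)])
        gs = simulate_genotypes(n, cfg.snp_specs, seed=0)
        conc, _, _ = simulate_concentrations(gs, cfg, seed=0)
        ro = simulate_ms_readouts(conc, cfg, seed=2)
        mult = ro.column("m1") / conc.column("m1")
        cv = mult.std(ddof=1) / mult.mean()
        assert abs(cv - 0.1) < 0.01


class TestDeterminism:
    def test_identical_seed_reproduces_bit_identical_cohort(self):
        cfg = _cfg(noise=NoiseSpec(1.0, 0.1, 0.0005),
                   ms_readout=[MsReadoutSpec("m1", cv=0.1, missing_rate=0.1)])
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a.spectra, b.spectra)
        assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
        assert np.array_equal(a.readouts.values, b.readouts.values,
                              equal_nan=True)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)


class TestRecoveryInvariant:
    def test_causal_snp_is_top_association_for_concentration(self):
        """Planted 0.1 log10 effect at MAF 0.3, n=1,757: generating SNP is
        the top association for the metabolite in >=95% of 20 seeds."""
        hitrate = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            specs = [SnpSpec(f"s{i}", "1", i + 1, float(rng.uniform(0.05, 0.5)))
                     for i in range(99)]
            specs.append(SnpSpec("causal", "2", 1, 0.3))
            cfg = SimulationConfig(
                n_subjects=1757, snp_specs=specs,
                metabolite_specs=[MetaboliteSpec("m1", 0.3, 0.10)],
                effect_specs=[EffectSpec("causal", "m1", 0.1)],
                peak_map=[PeakSpec("m1", 3.0, 0.002, 10.0)],
                seed=seed)
            gs = simulate_genotypes(cfg.n_subjects, cfg.snp_specs, seed=seed)
            conc, cov, _ = simulate_concentrations(gs, cfg, seed=seed + 500)
            y = np.log10(conc.column("m1"))
            res = assoc.scan_matrix(y[:, None], ["m1"], gs, cov)
            best = int(np.argmin(res["p"][0]))
            if gs.snps["id"].iloc[best] == "causal":
                hitrate += 1
        assert hitrate >= 0.95 * n_seeds


class TestYamlConfig:
    def test_simulation_config_from_yaml(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "n_subjects: 50\n"
            "seed: 3\n"
            "snp_specs:\n"
            "- {id: rs1, chrom: '1', pos: 100, maf: 0.3}\n"
            "metabolite_specs:\n"
            "- {name: m1, log_mean: 0.3, log_sd: 0.05}\n"
            "effect_specs:\n"
            "- {snp: rs1, metabolite: m1, beta: 0.1}\n"
            "peak_map:\n"
            "- {metabolite: m1, center: 3.0, half_width: 0.002, amplitude: 10}\n"
            "noise: {baseline_amplitude: 0, additive_sd: 0, shift_jitter_sd: 0}\n"
            "ms_readout:\n"
            "- {metabolite: m1, cv: 0.1, missing_rate: 0.0}\n")
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.n_subjects == 50
        assert cfg.snp_specs[0].maf == 0.3
        assert cfg.peak_map[0].offsets == (0.0,)
        cohort = simulate_cohort(cfg)
        assert cohort.spectra.shape[0] == 50
        assert cohort.readouts.names == ["m1"]
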