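"""Synthetic-data generator: structure, determinism and ground-truth scaling."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from growthgwas.growth import fit_curve, predict_weight
from growthgwas.simulate import (SimulationConfig, simulate_architecture,
                                 simulate_dataset, simulate_genotypes,
                                 simulate_weights)
from growthgwas.preadjust import adjust_weights

from conftest import MEAN_AGES, MEAN_WEIGHTS, WEIGHT_SDS


class TestGenotypes:
    def test_mean_genotype_matches_allele_frequency(self):
        # single SNP at p=0.5 in an unstructured population of 2000:
        # binomial SE of the mean genotype is sqrt(2*0.5*0.5/2000)
        cfg = SimulationConfig(n_individuals=2000, n_snps=1, n_subpops=1,
                               fst=0.0, maf_range=(0.5, 0.5), n_qtl=0, seed=1)
        G = simulate_genotypes(cfg).matrix
        assert abs(G.mean() - 1.0) < 0.07

    def test_no_missing_when_rate_zero(self):
        cfg = SimulationConfig(n_individuals=50, n_snps=100, missing_rate=0.0,
                               n_qtl=0, seed=2)
        assert not np.isnan(simulate_genotypes(cfg).matrix).any()

    def test_missing_rate_applied(self):
        cfg = SimulationConfig(n_individuals=200, n_snps=200, missing_rate=0.1,
                               n_qtl=0, seed=2)
        frac = np.isnan(simulate_genotypes(cfg).matrix).mean()
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_individuals=100, n_snps=300, missing_rate=0.05,
                               n_qtl=5, seed=77)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.matrix, b.matrix, equal_nan=True)
        assert list(a.subpop) == list(b.subpop)

    def test_allele_frequencies_within_configured_band(self):
        # unstructured draw: per-SNP sample frequency within the configured
        # MAF band up to 3 binomial SEs
        cfg = SimulationConfig(n_individuals=500, n_snps=400, n_subpops=1,
                               fst=0.0, maf_range=(0.1, 0.4), n_qtl=0, seed=4)
        G = simulate_genotypes(cfg).matrix
        freq = G.mean(axis=0) / 2.0
        se = np.sqrt(0.4 * 0.6 / (2 * 500))
        assert np.all(freq > 0.1 - 3 * se)
        assert np.all(freq < 0.4 + 3 * se)

    @pytest.mark.parametrize("field,kwargs", [
        ("n_individuals", {"n_individuals": 0}),
        ("maf_range", {"maf_range": (0.0, 0.6)}),
        ("n_qtl", {"n_qtl": 50, "n_snps": 10}),
        ("missing_rate", {"missing_rate": 1.5}),
        ("heritability_per_trait", {"heritability_per_trait": (1.0, 0.3, 0.3)}),
    ])
    def test_invalid_config_names_field(self, field, kwargs):
        with pytest.raises(ValueError, match=field):
            SimulationConfig(**kwargs)


class TestArchitecture:
    def test_zero_heritability_is_pure_environment(self):
        cfg = SimulationConfig(n_individuals=200, n_snps=100, n_qtl=5, seed=5,
                               heritability_per_trait=(0.0, 0.0, 0.0))
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        assert np.allclose(arch.genetic_values, 0.0)
        assert np.allclose(arch.polygenic_values, 0.0)

    def test_total_variance_matches_configuration(self):
        # no QTL: polygenic + environment should reconstruct the configured
        # total variance (cv * mean)^2 within 10% at n=1000
        cfg = SimulationConfig(n_individuals=1000, n_snps=500, n_qtl=0, seed=6,
                               heritability_per_trait=(0.4, 0.3, 0.3))
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        target = (np.array(cfg.param_cvs) * np.array(cfg.param_means)) ** 2
        sample = np.var(arch.true_params, axis=0, ddof=1)
        assert np.all(np.abs(sample / target - 1) < 0.10)

    def test_realised_heritability_tracks_configuration(self):
        cfg = SimulationConfig(n_individuals=800, n_snps=600, n_qtl=20, seed=8)
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        for k, h2 in enumerate(cfg.heritability_per_trait):
            realised = (np.var(arch.genetic_values[:, k], ddof=1)
                        / np.var(arch.true_params[:, k], ddof=1))
            assert realised == pytest.approx(h2, abs=0.05)

    def test_positive_parameters(self):
        cfg = SimulationConfig(n_individuals=500, n_snps=200, n_qtl=10, seed=9)
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        assert np.all(arch.true_params[:, 0] > 0)
        assert np.all(arch.true_params[:, 2] > 0)

    def test_qtl_more_than_snps_rejected(self):
        cfg = SimulationConfig(n_individuals=50, n_snps=20, n_qtl=5, seed=1)
        genos = simulate_genotypes(cfg).subset_snps(np.arange(3))
        with pytest.raises(ValueError, match="n_qtl"):
            simulate_architecture(genos, cfg)


class TestWeights:
    def test_noiseless_weight_matches_curve_value(self):
        # direct evaluation of the sigmoid at the reference estimates
        cfg = SimulationConfig(n_individuals=1, n_snps=10, n_qtl=0, seed=1,
                               heritability_per_trait=(0, 0, 0),
                               param_means=(617.9, 2.74, 0.153),
                               param_cvs=(0, 0, 0),
                               residual_weight_sd_by_age={0: 0, 6: 0, 12: 0, 18: 0},
                               fixed_effect_sds={"breed": 0, "birth_year": 0, "birth_month": 0})
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        rec = simulate_weights(arch, cfg)
        w12 = rec.loc[rec["age_months"] == 12, "weight_kg"].iloc[0]
        assert w12 == pytest.approx(399.19, abs=0.5)

    def test_large_age_approaches_asymptote(self):
        cfg = SimulationConfig(n_individuals=1, n_snps=10, n_qtl=0, seed=1,
                               heritability_per_trait=(0, 0, 0), param_cvs=(0, 0, 0),
                               ages_months=(600.0,),
                               residual_weight_sd_by_age={600.0: 0.0},
                               fixed_effect_sds={"breed": 0, "birth_year": 0, "birth_month": 0})
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        rec = simulate_weights(arch, cfg)
        A = cfg.param_means[0]
        assert abs(rec["weight_kg"].iloc[0] - A) < 1e-6 * A

    def test_per_age_means_match_reference_statistics(self):
        """Simulated (and pre-adjusted) per-age mean weights agree with the
        reference cohort means within 3 SEs when the curve-parameter means
        are tuned to those means by an SE-weighted fit."""
        n = 400
        se = WEIGHT_SDS / np.sqrt(n)
        tuned, _ = curve_fit(
            lambda t, A, b, K: A * np.exp(-b * np.exp(-K * t)),
            MEAN_AGES, MEAN_WEIGHTS, p0=(618, 2.74, 0.153), sigma=se, maxfev=20000)
        cfg = SimulationConfig(n_individuals=n, n_snps=100, n_qtl=5, seed=12,
                               param_means=tuple(tuned))
        _, _, rec = simulate_dataset(cfg)
        adjusted, _ = adjust_weights(rec)
        for age, mean, sd in zip(MEAN_AGES, MEAN_WEIGHTS, WEIGHT_SDS):
            sample = adjusted.loc[adjusted["age_months"] == age, "weight_kg"].mean()
            assert abs(sample - mean) < 3 * sd / np.sqrt(n), f"age {age}"

    def test_round_trip_zero_noise_recovers_parameters(self):
        """Fitting noiseless simulated weights recovers every animal's true
        (A, b, K) to at least 6 significant digits."""
        cfg = SimulationConfig(n_individuals=15, n_snps=50, n_qtl=3, seed=13,
                               residual_weight_sd_by_age={0: 0, 6: 0, 12: 0, 18: 0},
                               fixed_effect_sds={"breed": 0, "birth_year": 0, "birth_month": 0})
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg)
        rec = simulate_weights(arch, cfg)
        for i, ind in enumerate(f"ind{j + 1}" for j in range(cfg.n_individuals)):
            sub = rec[rec["id"] == ind]
            fit = fit_curve(sub["age_months"], sub["weight_kg"], model="gompertz")
            for est, true in zip((fit.A, fit.b, fit.K), arch.true_params[i]):
                assert est == pytest.approx(true, rel=1e-6)

    def test_determinism_end_to_end(self):
        cfg = SimulationConfig(n_individuals=60, n_snps=120, n_qtl=4, seed=21)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert np.array_equal(a[0].matrix, b[0].matrix, equal_nan=True)
        assert np.array_equal(a[1].true_params, b[1].true_params)
        assert a[2].equals(b[2])
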