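"""Growth-model evaluation, per-individual fitting and population selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from growthgwas.growth import (GrowthCurveModel, fit_curve, fit_population,
                               parameter_correlations, predict_weight, r_squared)

from conftest import MEAN_AGES, MEAN_WEIGHTS


class TestPredictWeight:
    @pytest.mark.parametrize("model,params,t,expected", [
        # closed-form evaluations at the reference parameter estimates
        ("gompertz", (617.9, 2.74, 0.153), 0.0, 617.9 * np.exp(-2.74)),
        ("logistic", (551.0, 9.304, 0.273), 0.0, 551.0 / (1 + 9.304)),
        ("brody", (1458.5, 0.976, 0.024), 0.0, 1458.5 * (1 - 0.976)),
    ])
    def test_closed_form_at_birth(self, model, params, t, expected):
        assert predict_weight(model, *params, t) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model", ["gompertz", "logistic", "brody"])
    def test_b_zero_collapses_to_asymptote(self, model):
        for t in (0.0, 7.3, 100.0):
            assert predict_weight(model, 500.0, 0.0, 0.2, t) == pytest.approx(500.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown growth model"):
            predict_weight("richards", 500, 1, 0.1, 0)

    @given(st.floats(100, 1000), st.floats(0.5, 5), st.floats(0.05, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gompertz_monotone_with_asymptote(self, A, b, K):
        t = np.linspace(0, 60, 200)
        w = predict_weight("gompertz", A, b, K, t)
        assert np.all(np.diff(w) > 0)
        assert predict_weight("gompertz", A, b, K, 600.0) == pytest.approx(A, rel=1e-6)


class TestRSquared:
    def test_exact_fit_is_one(self):
        w = np.array([1.0, 2.0, 5.0])
        assert r_squared(w, w) == 1.0

    def test_mean_prediction_is_zero(self):
        w = np.array([1.0, 2.0, 5.0])
        assert r_squared(w, np.full(3, w.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_observed_flagged(self):
        with pytest.raises(ValueError, match="SST = 0"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, c):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        fit = np.array([1.1, 1.9, 4.2, 7.6])
        assert r_squared(a * obs + c, a * fit + c) == pytest.approx(
            r_squared(obs, fit), rel=1e-9)


class TestFitCurve:
    @pytest.mark.parametrize("model,params", [
        ("gompertz", (500.0, 3.0, 0.2)),
        ("logistic", (500.0, 9.0, 0.27)),
        ("brody", (500.0, 0.9, 0.15)),   # Brody needs b < 1 for positive birth weight
    ])
    def test_zero_noise_recovery_to_machine_precision(self, model, params):
        """Generating parameters are the global optimum of noiseless data."""
        A, b, K = params
        t = np.arange(0, 19, 3, dtype=float)
        w = predict_weight(model, A, b, K, t)
        fit = fit_curve(t, w, model=model)
        assert fit.rss < 1e-10
        assert fit.converged
        assert fit.A == pytest.approx(A, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.K == pytest.approx(K, rel=1e-6)

    def test_brody_optimum_matches_grid_search_oracle(self):
        """Dense grid + local polish bounds the Brody fit on the mean weights."""
        best = (np.inf, None)
        for A in np.linspace(600, 2500, 96):
            for bb in np.linspace(0.9, 1.0, 21):
                for K in np.linspace(0.01, 0.05, 41):
                    r = MEAN_WEIGHTS - A * (1 - bb * np.exp(-K * MEAN_AGES))
                    rss = float(r @ r)
                    if rss < best[0]:
                        best = (rss, (A, bb, K))
        polish = minimize(
            lambda th: float(np.sum((MEAN_WEIGHTS - th[0] * (1 - th[1] * np.exp(-th[2] * MEAN_AGES))) ** 2)),
            best[1], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        fit = fit_curve(MEAN_AGES, MEAN_WEIGHTS, model="brody")
        assert fit.rss <= polish.fun * (1 + 1e-6)
        assert fit.A == pytest.approx(polish.x[0], rel=1e-3)

    def test_gauss_newton_matches_simplex_oracle(self):
        """GN RSS agrees with a derivative-free simplex optimum on random series."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            A = rng.uniform(300, 900)
            b = rng.uniform(1.5, 4.0)
            K = rng.uniform(0.08, 0.3)
            t = np.array([0.0, 6.0, 12.0, 18.0])
            w = predict_weight("gompertz", A, b, K, t) + rng.normal(0, 10, 4)
            w = np.maximum(w, 1.0)
            fit = fit_curve(t, w, model="gompertz")
            oracle = minimize(
                lambda th: float(np.sum((w - th[0] * np.exp(-th[1] * np.exp(-th[2] * t))) ** 2)),
                [fit.A * 1.05, fit.b * 1.1, fit.K * 0.9], method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000})
            assert fit.rss <= oracle.fun * (1 + 1e-6) + 1e-9

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            fit_curve([0, 0, 6], [30, 31, 200], model="gompertz")

    def test_explicit_init_honoured(self):
        fit = fit_curve(MEAN_AGES, MEAN_WEIGHTS, model="gompertz",
                        init=(600.0, 2.5, 0.15))
        assert fit.A == pytest.approx(617.9, rel=0.02)

    def test_sklearn_estimator_interface(self):
        t = np.array([0.0, 6.0, 12.0, 18.0])
        w = predict_weight("gompertz", 500, 3, 0.2, t)
        est = GrowthCurveModel(model="gompertz").fit(t.reshape(-1, 1), w)
        assert est.converged_
        assert est.predict([[24.0]])[0] == pytest.approx(
            predict_weight("gompertz", 500, 3, 0.2, 24.0), rel=1e-6)
        assert est.get_params()["model"] == "gompertz"


class TestFitPopulation:
    @staticmethod
    def _records(rng, n, noise=5.0):
        rows = []
        for i in range(n):
            A = rng.uniform(450, 750)
            b = rng.uniform(2.2, 3.2)
            K = rng.uniform(0.1, 0.25)
            for t in (0.0, 6.0, 12.0, 18.0):
                w = predict_weight("gompertz", A, b, K, t) + rng.normal(0, noise)
                rows.append({"id": f"i{i}", "age_months": t, "weight_kg": max(w, 1.0)})
        return pd.DataFrame(rows)

    def test_generating_model_selected(self):
        records = self._records(np.random.default_rng(5), 50)
        pop = fit_population(records)
        assert pop.selected_model == "gompertz"
        assert pop.pooled_r2["gompertz"] >= max(pop.pooled_r2.values()) - 1e-12
        assert set(pop.phenotypes.columns) == {"id", "A", "b", "K"}

    def test_single_individual_pooled_equals_own_r2(self):
        records = self._records(np.random.default_rng(6), 1)
        pop = fit_population(records, models=("gompertz",))
        own = pop.fits.iloc[0]["r_squared"]
        assert pop.pooled_r2["gompertz"] == pytest.approx(own, rel=1e-9)

    def test_zero_noise_pooled_r2_is_one(self):
        records = self._records(np.random.default_rng(7), 10, noise=0.0)
        pop = fit_population(records, models=("gompertz",))
        assert pop.pooled_r2["gompertz"] == pytest.approx(1.0, abs=1e-9)


class TestParameterCorrelations:
    def test_identical_columns_correlate_fully(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        df = pd.DataFrame({"A": x, "b": [5, 1, 2, 7.0], "K": x})
        corr = parameter_correlations(df)
        assert corr.loc["A", "K"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_exact_antirank(self):
        df = pd.DataFrame({"A": [1.0, 2, 3], "b": [3.0, 2, 1], "K": [1.0, 5, 2]})
        assert parameter_correlations(df).loc["A", "b"] == pytest.approx(-1.0)

    def test_opposite_sign_pleiotropy_gives_negative_correlation(self, small_sim):
        """A shared causal allele with opposing effects on A and K forces
        a negative correlation between their genetic values."""
        from growthgwas.simulate import SimulationConfig, simulate_architecture, simulate_genotypes
        cfg = SimulationConfig(n_individuals=400, n_snps=50, n_qtl=1, seed=9,
                               heritability_per_trait=(0.6, 0.6, 0.6),
                               qtl_variance_share=1.0)
        genos = simulate_genotypes(cfg)
        arch = simulate_architecture(genos, cfg, qtl_indices=[10],
                                     qtl_effects=[[1.0, 1.0, -1.0]])
        g = arch.genetic_values
        assert np.corrcoef(g[:, 0], g[:, 2])[0, 1] < 0
        df = pd.DataFrame(arch.true_params, columns=["A", "b", "K"])
        assert parameter_correlations(df).loc["A", "K"] < 0
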